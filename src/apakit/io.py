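"""Readers and writers for APA quantification dialects and companion tables.

Three tabular dialects are supported:

* **qapa** — per-transcript rows with 3'UTR coordinates, per-sample
  expression columns identified by a terminal ``TPM`` token and usage
  columns by a terminal ``PAU`` token.
* **dapars** — per-transcript rows whose ``Gene`` field encodes
  ``transcript|gene|chrom|strand``, with a predicted proximal APA
  coordinate, a ``chrom:start-end`` 3'UTR locus, and per-sample columns
  identified by a terminal ``PDUI`` token (``NA`` cells are missing).
* **generic** — a documented minimal dialect (feature_id, gene_symbol,
  chrom, strand, proximal_pos, distal_pos, then one usage column per
  sample) for quantifications produced by other methods.

All writers are round-trip safe: parsing what they write reproduces the
dataset field-for-field. BED output is 0-based half-open with strand in
column 6; cleavage positions are converted from their 1-based in-memory
form at this boundary only.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .model import (
    APAError,
    APASite,
    ClinicalTable,
    ExpressionMatrix,
    ParseError,
    UsageMatrix,
    UTRRegion,
    order_sites,
)

_SEPARATORS = (".", "_")


@dataclass
class APADataset:
    """A parsed APA quantification: sites, UTRs, usage, optional expression."""

    sites: list[APASite]
    utrs: list[UTRRegion]
    usage: UsageMatrix
    transcript_expression: ExpressionMatrix | None = None
    source: str = "generic"

    def __post_init__(self) -> None:
        if self.source not in ("qapa", "dapars", "generic"):
            raise APAError(f"unknown source {self.source!r}")
        known = {s.site_id for s in self.sites}
        known |= {s.gene_id for s in self.sites}
        known |= {s.transcript_id for s in self.sites}
        unresolved = [f for f in self.usage.feature_ids if f not in known]
        if unresolved:
            raise APAError(
                f"usage features not present among sites: {unresolved[:5]}"
            )

    def sites_by_gene(self) -> dict[str, list[APASite]]:
        out: dict[str, list[APASite]] = {}
        for s in self.sites:
            out.setdefault(s.gene_id, []).append(s)
        return out

    def gene_usage(self) -> UsageMatrix:
        """Collapse usage to one row per gene with higher-is-longer polarity.

        For QAPA data the gene-level value is the PAU of the distal-ranked
        transcript, so that a larger value always means a longer 3'UTR,
        matching the polarity of PDUI. DaPars/generic usage is already one
        row per transcript and is re-indexed by gene id.
        """
        rows = {}
        if self.source == "qapa":
            for gene, sites in self.sites_by_gene().items():
                distal = [s for s in sites if s.rank in ("distal", "single")]
                if not distal:
                    continue
                fid = distal[0].site_id
                if fid in self.usage.values.index:
                    rows[gene] = self.usage.values.loc[fid]
        else:
            by_feature = {}
            for s in self.sites:
                by_feature.setdefault(s.transcript_id, s.gene_id)
                by_feature.setdefault(s.site_id, s.gene_id)
            for fid in self.usage.feature_ids:
                gene = by_feature.get(fid, fid)
                if gene not in rows:
                    rows[gene] = self.usage.values.loc[fid]
        values = pd.DataFrame(rows).T
        values.columns = self.usage.values.columns
        return UsageMatrix(kind=self.usage.kind, values=values)


class BedInterval(NamedTuple):
    """A named 0-based half-open genomic interval (BED semantics)."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: str = "."
    strand: str = "."


# ---------------------------------------------------------------------------
# column resolution helpers


def _read_table(source) -> pd.DataFrame:
    try:
        df = pd.read_csv(source, sep="\t", dtype=str, encoding="utf-8")
    except (pd.errors.ParserError, UnicodeDecodeError, pd.errors.EmptyDataError) as e:
        raise ParseError(f"cannot read table: {e}") from e
    if df.columns.size == 0:
        raise ParseError("table has no header row")
    return df


def _resolve(columns: Sequence[str], synonyms: Sequence[str], what: str) -> str:
    for name in synonyms:
        if name in columns:
            return name
    raise ParseError(f"missing mandatory column for {what}; expected one of {list(synonyms)}")


def _suffix_samples(columns: Sequence[str], suffix: str) -> dict[str, str]:
    """Map sample id -> column name for columns ending in ``<sep><suffix>``."""
    out: dict[str, str] = {}
    for col in columns:
        for sep in _SEPARATORS:
            tail = sep + suffix
            if col.endswith(tail) and len(col) > len(tail):
                out[col[: -len(tail)]] = col
                break
    return out


def _float_cell(raw, row: int, col: str) -> float:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan
    s = str(raw).strip()
    if s in ("", "NA", "NaN", "nan", "None"):
        return np.nan
    if "," in s:
        raise ParseError(f"row {row}, column {col!r}: comma-decimal {s!r} not accepted")
    try:
        return float(s)
    except ValueError as e:
        raise ParseError(f"row {row}, column {col!r}: not a number: {s!r}") from e


def _numeric_block(df: pd.DataFrame, colmap: dict[str, str], *, lo=None, hi=None,
                   what: str) -> pd.DataFrame:
    data = {}
    for sample, col in colmap.items():
        vals = [ _float_cell(v, i, col) for i, v in enumerate(df[col]) ]
        for i, v in enumerate(vals):
            if np.isnan(v):
                continue
            if (lo is not None and v < lo) or (hi is not None and v > hi):
                rng = f"[{lo}, {hi}]" if hi is not None else f">= {lo}"
                raise ParseError(
                    f"row {i}, column {col!r}: {what} value {v} outside {rng}"
                )
        data[sample] = vals
    return pd.DataFrame(data, index=df.index)


def _int_cell(raw, row: int, col: str) -> int:
    v = _float_cell(raw, row, col)
    if np.isnan(v) or v != int(v):
        raise ParseError(f"row {row}, column {col!r}: expected an integer, got {raw!r}")
    return int(v)


# ---------------------------------------------------------------------------
# QAPA dialect


_QAPA_COLS = {
    "apa_id": ("APA_ID", "APA_id"),
    "transcript": ("Transcript", "Transcript_ID"),
    "gene": ("Gene", "Gene_ID"),
    "gene_name": ("Gene_Name", "Gene_Symbol"),
    "chrom": ("Chr", "Chrom", "Chromosome"),
    "strand": ("Strand",),
    "utr_start": ("UTR3.Start", "UTR3_Start", "LastExon.Start"),
    "utr_end": ("UTR3.End", "UTR3_End", "LastExon.End"),
}


def parse_qapa(source) -> APADataset:
    """Parse a QAPA output table into an :class:`APADataset`.

    Sample expression/usage columns are identified by their terminal
    ``TPM``/``PAU`` token; the sample id is the column name with the
    suffix stripped. The TPM and PAU column sets must name the same
    samples.
    """
    df = _read_table(source)
    cols = {k: _resolve(df.columns, syn, k) for k, syn in _QAPA_COLS.items()}
    tpm_map = _suffix_samples(df.columns, "TPM")
    pau_map = _suffix_samples(df.columns, "PAU")
    if not pau_map:
        raise ParseError("no PAU-suffixed sample columns found")
    if set(tpm_map) != set(pau_map):
        raise ParseError(
            "TPM and PAU sample sets disagree: "
            f"TPM-only={sorted(set(tpm_map) - set(pau_map))}, "
            f"PAU-only={sorted(set(pau_map) - set(tpm_map))}"
        )
    sample_ids = sorted(pau_map)

    sites: list[APASite] = []
    utrs: list[UTRRegion] = []
    raw_sites = []
    for i, row in df.iterrows():
        strand = str(row[cols["strand"]]).strip()
        start = _int_cell(row[cols["utr_start"]], i, cols["utr_start"])
        end = _int_cell(row[cols["utr_end"]], i, cols["utr_end"])
        cleavage = end if strand == "+" else start + 1
        apa_id = str(row[cols["apa_id"]]).strip()
        raw_sites.append(
            APASite(
                site_id=apa_id,
                gene_id=str(row[cols["gene"]]).strip(),
                gene_symbol=str(row[cols["gene_name"]]).strip(),
                transcript_id=str(row[cols["transcript"]]).strip(),
                chrom=str(row[cols["chrom"]]).strip(),
                strand=strand,
                cleavage_pos=cleavage,
            )
        )
        utrs.append(
            UTRRegion(
                transcript_id=str(row[cols["transcript"]]).strip(),
                chrom=str(row[cols["chrom"]]).strip(),
                strand=strand,
                start=start,
                end=end,
            )
        )
    # rank sites within each gene by sense-strand order
    by_gene: dict[str, list[APASite]] = {}
    for s in raw_sites:
        by_gene.setdefault(s.gene_id, []).append(s)
    ranked = {s.site_id: s for g in by_gene.values() for s in order_sites(g)}
    sites = [ranked[s.site_id] for s in raw_sites]

    pau = _numeric_block(df, {s: pau_map[s] for s in sample_ids}, lo=0, hi=1, what="PAU")
    tpm = _numeric_block(df, {s: tpm_map[s] for s in sample_ids}, lo=0, what="TPM")
    fids = [s.site_id for s in sites]
    pau.index = fids
    tpm.index = fids
    return APADataset(
        sites=sites,
        utrs=utrs,
        usage=UsageMatrix(kind="PAU", values=pau),
        transcript_expression=ExpressionMatrix(values=tpm),
        source="qapa",
    )


# ---------------------------------------------------------------------------
# DaPars dialect


_DAPARS_COLS = {
    "gene": ("Gene",),
    "proximal": ("Predicted_Proximal_APA",),
    "loci": ("Loci",),
}


def _parse_locus(raw: str, row: int) -> tuple[str, int, int]:
    s = str(raw).strip()
    try:
        chrom, span = s.split(":")
        a, b = span.split("-")
        start, end = int(a), int(b)
    except ValueError as e:
        raise ParseError(
            f"row {row}: malformed locus {s!r}; expected 'chrom:start-end'"
        ) from e
    if start >= end:
        raise ParseError(f"row {row}: locus {s!r} has start >= end")
    return chrom, start, end


def parse_dapars(source) -> APADataset:
    """Parse a DaPars output table into an :class:`APADataset`.

    Each row yields two sites: the predicted proximal APA coordinate, and
    a distal site at the 3'UTR end (locus end on ``+``, locus start on
    ``-``). ``NA`` PDUI cells are stored as missing, not rejected.
    """
    df = _read_table(source)
    cols = {k: _resolve(df.columns, syn, k) for k, syn in _DAPARS_COLS.items()}
    pdui_map = _suffix_samples(df.columns, "PDUI")
    if not pdui_map:
        raise ParseError("no PDUI-suffixed sample columns found")
    sample_ids = sorted(pdui_map)

    sites: list[APASite] = []
    utrs: list[UTRRegion] = []
    feature_ids: list[str] = []
    for i, row in df.iterrows():
        gene_field = str(row[cols["gene"]]).strip()
        parts = gene_field.split("|")
        if len(parts) != 4:
            raise ParseError(
                f"row {i}: gene field {gene_field!r} must encode "
                "'transcript|gene|chrom|strand'"
            )
        tx, gene, chrom_g, strand = parts
        chrom, start, end = _parse_locus(row[cols["loci"]], i)
        if chrom != chrom_g:
            raise ParseError(
                f"row {i}: locus chromosome {chrom!r} disagrees with gene field {chrom_g!r}"
            )
        proximal_pos = _int_cell(row[cols["proximal"]], i, cols["proximal"])
        distal_pos = end if strand == "+" else start
        common = dict(gene_id=gene, gene_symbol=gene, transcript_id=tx,
                      chrom=chrom, strand=strand)
        sites.append(APASite(site_id=f"{tx}_P", cleavage_pos=proximal_pos,
                             rank="proximal", **common))
        sites.append(APASite(site_id=f"{tx}_D", cleavage_pos=distal_pos,
                             rank="distal", **common))
        utrs.append(UTRRegion(transcript_id=tx, chrom=chrom, strand=strand,
                              start=start - 1, end=end))
        feature_ids.append(tx)

    pdui = _numeric_block(df, {s: pdui_map[s] for s in sample_ids}, lo=0, hi=1,
                          what="PDUI")
    pdui.index = feature_ids
    return APADataset(
        sites=sites,
        utrs=utrs,
        usage=UsageMatrix(kind="PDUI", values=pdui),
        source="dapars",
    )


# ---------------------------------------------------------------------------
# generic dialect


_GENERIC_FIXED = ["feature_id", "gene_symbol", "chrom", "strand",
                  "proximal_pos", "distal_pos"]


def parse_generic(source, kind: str = "PDUI") -> APADataset:
    """Parse the documented minimal dialect for other quantification methods.

    Columns: ``feature_id  gene_symbol  chrom  strand  proximal_pos
    distal_pos`` followed by one usage column per sample. Usage polarity
    must be higher-is-longer; positions are 1-based cleavage coordinates.
    """
    df = _read_table(source)
    for col in _GENERIC_FIXED:
        if col not in df.columns:
            raise ParseError(f"missing mandatory column for {col}; expected one of ['{col}']")
    sample_cols = [c for c in df.columns if c not in _GENERIC_FIXED]
    if not sample_cols:
        raise ParseError("no per-sample usage columns found")

    sites: list[APASite] = []
    utrs: list[UTRRegion] = []
    feature_ids: list[str] = []
    for i, row in df.iterrows():
        fid = str(row["feature_id"]).strip()
        strand = str(row["strand"]).strip()
        prox = _int_cell(row["proximal_pos"], i, "proximal_pos")
        dist = _int_cell(row["distal_pos"], i, "distal_pos")
        common = dict(gene_id=fid, gene_symbol=str(row["gene_symbol"]).strip(),
                      transcript_id=fid, chrom=str(row["chrom"]).strip(),
                      strand=strand)
        sites.append(APASite(site_id=f"{fid}_P", cleavage_pos=prox,
                             rank="proximal", **common))
        sites.append(APASite(site_id=f"{fid}_D", cleavage_pos=dist,
                             rank="distal", **common))
        lo, hi = sorted((prox, dist))
        utrs.append(UTRRegion(transcript_id=fid, chrom=common["chrom"],
                              strand=strand, start=lo - 1, end=hi))
        feature_ids.append(fid)

    usage = _numeric_block(df, {c: c for c in sample_cols}, lo=0, hi=1, what="usage")
    usage.index = feature_ids
    return APADataset(sites=sites, utrs=utrs,
                      usage=UsageMatrix(kind=kind, values=usage),
                      source="generic")


def parse_apa(source, dialect: str) -> APADataset:
    """Dispatch to the dialect parser for ``qapa``, ``dapars`` or ``generic``."""
    parsers = {"qapa": parse_qapa, "dapars": parse_dapars, "generic": parse_generic}
    if dialect not in parsers:
        raise APAError(f"unknown dialect {dialect!r}; expected one of {sorted(parsers)}")
    return parsers[dialect](source)


# ---------------------------------------------------------------------------
# companion tables


def parse_expression(source) -> ExpressionMatrix:
    """Read a features x samples TPM matrix (first column = feature id)."""
    df = _read_table(source)
    if df.columns.size < 2:
        raise ParseError("expression table needs a feature column plus >= 1 sample")
    fid_col = df.columns[0]
    sample_cols = list(df.columns[1:])
    block = _numeric_block(df, {c: c for c in sample_cols}, lo=0, what="TPM")
    block.index = [str(v).strip() for v in df[fid_col]]
    return ExpressionMatrix(values=block)


def parse_clinical(source, time_column: str = "time", event_column: str = "event",
                   time_unit: str = "days") -> ClinicalTable:
    """Read a clinical table (first column = sample id) with survival columns."""
    df = _read_table(source)
    fid_col = df.columns[0]
    ids = [str(v).strip() for v in df[fid_col]]
    if len(set(ids)) != len(ids):
        dups = sorted({x for x in ids if ids.count(x) > 1})
        raise ParseError(f"duplicate sample IDs in clinical table: {dups}")
    for col in (time_column, event_column):
        if col not in df.columns:
            raise ParseError(f"missing mandatory column for {col}; expected one of ['{col}']")
    out = df.drop(columns=[fid_col]).copy()
    out.index = ids
    out[time_column] = [_float_cell(v, i, time_column) for i, v in enumerate(out[time_column])]
    out[event_column] = [_float_cell(v, i, event_column) for i, v in enumerate(out[event_column])]
    return ClinicalTable(table=out, time_column=time_column,
                         event_column=event_column, time_unit=time_unit)


def parse_bed(source) -> list[BedInterval]:
    """Read a BED track (>= 3 columns, 0-based half-open) into intervals."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    out: list[BedInterval] = []
    for ln, line in enumerate(text.splitlines()):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(f"BED line {ln}: fewer than 3 columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as e:
            raise ParseError(f"BED line {ln}: non-integer coordinates") from e
        if start >= end:
            raise ParseError(f"BED line {ln}: start >= end")
        out.append(BedInterval(
            chrom=parts[0], start=start, end=end,
            name=parts[3] if len(parts) > 3 else ".",
            score=parts[4] if len(parts) > 4 else ".",
            strand=parts[5] if len(parts) > 5 else ".",
        ))
    return out


# ---------------------------------------------------------------------------
# writers


def write_results_tsv(table: pd.DataFrame, dest) -> None:
    """Write any result table as TSV with ``NA`` for missing cells."""
    table.to_csv(dest, sep="\t", index=False, na_rep="NA")


def write_bed(items: Iterable[APASite | UTRRegion | BedInterval], dest) -> None:
    """Write sites/UTRs as BED6 (cleavage positions become 1-length intervals)."""
    lines = []
    for it in items:
        if isinstance(it, APASite):
            lines.append(f"{it.chrom}\t{it.cleavage_pos - 1}\t{it.cleavage_pos}"
                         f"\t{it.site_id}\t.\t{it.strand}")
        elif isinstance(it, UTRRegion):
            lines.append(f"{it.chrom}\t{it.start}\t{it.end}"
                         f"\t{it.transcript_id}\t.\t{it.strand}")
        else:
            lines.append(f"{it.chrom}\t{it.start}\t{it.end}"
                         f"\t{it.name}\t{it.score}\t{it.strand}")
    text = "\n".join(lines) + ("\n" if lines else "")
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        with open(dest, "w", encoding="utf-8") as fh:
            fh.write(text)


def write_qapa(dataset: APADataset, dest) -> None:
    """Write a dataset in the QAPA dialect (requires transcript expression)."""
    if dataset.transcript_expression is None:
        raise APAError("QAPA dialect requires a transcript expression matrix")
    n_events = {g: len(ss) for g, ss in dataset.sites_by_gene().items()}
    utr_by_tx = {u.transcript_id: u for u in dataset.utrs}
    rows = []
    for s in dataset.sites:
        u = utr_by_tx[s.transcript_id]
        rows.append({
            "APA_ID": s.site_id, "Transcript": s.transcript_id,
            "Gene": s.gene_id, "Gene_Name": s.gene_symbol,
            "Chr": s.chrom, "Strand": s.strand,
            "UTR3.Start": u.start, "UTR3.End": u.end, "Length": u.length,
            "Num_Events": n_events[s.gene_id],
        })
    df = pd.DataFrame(rows)
    for sample in dataset.usage.sample_ids:
        df[f"{sample}.TPM"] = dataset.transcript_expression.values[sample].to_numpy()
        df[f"{sample}.PAU"] = dataset.usage.values[sample].to_numpy()
    df.to_csv(dest, sep="\t", index=False, na_rep="NA")


def write_dapars(dataset: APADataset, dest) -> None:
    """Write a dataset in the DaPars dialect (one row per usage feature)."""
    prox = {s.transcript_id: s for s in dataset.sites if s.rank == "proximal"}
    utr_by_tx = {u.transcript_id: u for u in dataset.utrs}
    rows = []
    for fid in dataset.usage.feature_ids:
        s = prox.get(fid)
        if s is None:
            raise APAError(f"feature {fid!r} has no proximal site; cannot emit DaPars row")
        u = utr_by_tx[fid]
        rows.append({
            "Gene": f"{s.transcript_id}|{s.gene_id}|{s.chrom}|{s.strand}",
            "Predicted_Proximal_APA": s.cleavage_pos,
            "Loci": f"{u.chrom}:{u.start + 1}-{u.end}",
        })
    df = pd.DataFrame(rows)
    for sample in dataset.usage.sample_ids:
        df[f"{sample}_PDUI"] = dataset.usage.values[sample].to_numpy()
    df.to_csv(dest, sep="\t", index=False, na_rep="NA")


def write_generic(dataset: APADataset, dest) -> None:
    """Write a dataset in the generic dialect."""
    by_rank: dict[str, dict[str, APASite]] = {"proximal": {}, "distal": {}}
    for s in dataset.sites:
        if s.rank in by_rank:
            by_rank[s.rank][s.transcript_id] = s
    rows = []
    for fid in dataset.usage.feature_ids:
        p, d = by_rank["proximal"].get(fid), by_rank["distal"].get(fid)
        if p is None or d is None:
            raise APAError(f"feature {fid!r} lacks a proximal/distal site pair")
        rows.append({
            "feature_id": fid, "gene_symbol": p.gene_symbol, "chrom": p.chrom,
            "strand": p.strand, "proximal_pos": p.cleavage_pos,
            "distal_pos": d.cleavage_pos,
        })
    df = pd.DataFrame(rows)
    for sample in dataset.usage.sample_ids:
        df[sample] = dataset.usage.values[sample].to_numpy()
    df.to_csv(dest, sep="\t", index=False, na_rep="NA")


def write_apa(dataset: APADataset, dialect: str, dest) -> None:
    """Dispatch to the dialect writer."""
    writers = {"qapa": write_qapa, "dapars": write_dapars, "generic": write_generic}
    if dialect not in writers:
        raise APAError(f"unknown dialect {dialect!r}; expected one of {sorted(writers)}")
    writers[dialect](dataset, dest)
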