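"""In-memory data model for alternative-polyadenylation (APA) analysis.

The model is shared by all analysis stages and is independent of whether
the quantification came from QAPA (transcript-level PAU) or DaPars
(gene/transcript-level PDUI).

Coordinate conventions
----------------------
Genomic intervals (:class:`UTRRegion`) are stored 0-based half-open, the
convention of BED. Cleavage positions (:class:`APASite.cleavage_pos`) are
stored 1-based, matching how site coordinates are printed in browsers and
publications. Conversion between the two happens only at I/O boundaries.

Usage values (PAU or PDUI) live in [0, 1]; missing values are first-class
(stored as NaN, never imputed) and every statistic drops them pairwise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class APAError(ValueError):
    """Base class for all apakit data/validation errors."""


class ParseError(APAError):
    """Malformed or contract-violating input data."""


VALID_RANKS = ("proximal", "distal", "internal", "single")
VALID_STRANDS = ("+", "-")


@dataclass(frozen=True)
class APASite:
    """One cleavage/polyadenylation site with strand-aware rank.

    ``rank`` orders sites along the transcript's sense direction:
    *proximal* is nearest the stop codon, *distal* is farthest, sites in
    between are *internal*, and a gene with one site has rank *single*.
    """

    site_id: str
    gene_id: str
    gene_symbol: str
    transcript_id: str
    chrom: str
    strand: str
    cleavage_pos: int  # 1-based genomic coordinate
    rank: str = "single"

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise APAError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.cleavage_pos < 1:
            raise APAError(f"cleavage_pos must be >= 1, got {self.cleavage_pos}")
        if self.rank not in VALID_RANKS:
            raise APAError(f"rank must be one of {VALID_RANKS}, got {self.rank!r}")


@dataclass(frozen=True)
class UTRRegion:
    """A 3'UTR genomic interval, 0-based half-open."""

    transcript_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise APAError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise APAError(
                f"UTR interval must satisfy start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise APAError(f"duplicate {what}: {dups[:5]}")


@dataclass
class UsageMatrix:
    """Features x samples matrix of PAU or PDUI values in [0, 1].

    ``values`` is a DataFrame indexed by feature id with sample-id columns;
    NaN marks a missing measurement (e.g. a low-coverage DaPars sample).
    """

    kind: str  # "PAU" or "PDUI"
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.kind not in ("PAU", "PDUI"):
            raise APAError(f"usage kind must be 'PAU' or 'PDUI', got {self.kind!r}")
        _check_unique(list(self.values.index), "feature ids")
        _check_unique(list(self.values.columns), "sample ids")
        vals = self.values.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if np.any(bad & ~np.isnan(vals)):
            i, j = np.argwhere(bad & ~np.isnan(vals))[0]
            raise APAError(
                f"usage value out of [0,1]: {vals[i, j]} at feature "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def row(self, feature_id: str) -> pd.Series:
        if feature_id not in self.values.index:
            raise KeyError(f"unknown feature {feature_id!r}")
        return self.values.loc[feature_id]


@dataclass
class ExpressionMatrix:
    """Features x samples TPM matrix; non-missing entries are >= 0."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(list(self.values.index), "feature ids")
        _check_unique(list(self.values.columns), "sample ids")
        vals = self.values.to_numpy(dtype=float)
        neg = vals < 0
        if np.any(neg & ~np.isnan(vals)):
            i, j = np.argwhere(neg & ~np.isnan(vals))[0]
            raise APAError(
                f"negative TPM {vals[i, j]} at feature {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def row(self, feature_id: str) -> pd.Series:
        if feature_id not in self.values.index:
            raise KeyError(f"unknown feature {feature_id!r}")
        return self.values.loc[feature_id]


@dataclass
class ClinicalTable:
    """Per-sample covariates plus right-censored survival data.

    ``table`` is indexed by sample id; ``time_unit`` records the declared
    unit (days or months) and is never converted.
    """

    table: pd.DataFrame  # indexed by sample_id
    time_column: str = "time"
    event_column: str = "event"
    time_unit: str = "days"

    def __post_init__(self) -> None:
        _check_unique(list(self.table.index), "sample ids")
        for col in (self.time_column, self.event_column):
            if col not in self.table.columns:
                raise APAError(f"clinical table lacks column {col!r}")
        t = self.table[self.time_column].astype(float)
        if (t.dropna() < 0).any():
            bad = self.table.index[t < 0][0]
            raise APAError(f"negative survival_time for sample {bad!r}")
        ev = self.table[self.event_column].dropna()
        if not ev.isin([0, 1, 0.0, 1.0, "0", "1", True, False]).all():
            raise APAError("event indicator must be 0 (censored) or 1 (event)")
        self.table[self.event_column] = self.table[self.event_column].astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def times(self) -> pd.Series:
        return self.table[self.time_column].astype(float)

    @property
    def events(self) -> pd.Series:
        return self.table[self.event_column].astype(int)


@dataclass
class GroupAssignment:
    """Mapping sample id -> group label, with a declared label order.

    The label order fixes the sign convention of mean differences
    (delta = mean(first) - mean(second)).
    """

    mapping: Mapping[str, str]
    order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        labels = list(dict.fromkeys(self.mapping.values()))
        if not self.order:
            self.order = tuple(labels)
        if len(self.order) < 2:
            raise APAError("a grouping needs at least 2 distinct group labels")
        for lab in self.order:
            if not any(v == lab for v in self.mapping.values()):
                raise APAError(f"group {lab!r} is empty")
        extra = set(labels) - set(self.order)
        if extra:
            raise APAError(f"samples assigned to undeclared groups: {sorted(extra)}")

    @property
    def labels(self) -> tuple[str, ...]:
        return self.order

    def samples(self, label: str) -> list[str]:
        return [s for s, g in self.mapping.items() if g == label]

    def __len__(self) -> int:
        return len(self.mapping)


def order_sites(sites: Sequence[APASite], utr_anchor: int | None = None) -> list[APASite]:
    """Assign proximal/distal/internal/single ranks to one gene's sites.

    Sites are ordered along the sense strand: on ``+`` the smallest
    cleavage position is proximal (nearest the shared 3'UTR start), on
    ``-`` the largest is proximal. The returned list is in sense order
    (proximal first) regardless of input order.

    Parameters
    ----------
    sites
        All APA sites of a single gene; must share gene, chromosome and
        strand.
    utr_anchor
        Optional 0-based sense-strand 3'UTR start shared by the isoforms;
        when given, every site must lie downstream of it.
    """
    if not sites:
        raise APAError("order_sites requires at least one site")
    genes = {s.gene_id for s in sites}
    chroms = {s.chrom for s in sites}
    strands = {s.strand for s in sites}
    if len(genes) > 1 or len(chroms) > 1 or len(strands) > 1:
        raise APAError(
            "sites must share gene, chromosome and strand; got "
            f"genes={sorted(genes)}, chroms={sorted(chroms)}, strands={sorted(strands)}"
        )
    strand = sites[0].strand
    if utr_anchor is not None:
        for s in sites:
            downstream = s.cleavage_pos > utr_anchor if strand == "+" else s.cleavage_pos <= utr_anchor
            if not downstream:
                raise APAError(
                    f"site {s.site_id!r} at {s.cleavage_pos} lies upstream of the "
                    f"3'UTR anchor {utr_anchor} on strand {strand}"
                )
    # deterministic under permutation: sort by sense position, site_id breaks ties
    sign = -1 if strand == "-" else 1
    sense = sorted(sites, key=lambda s: (sign * s.cleavage_pos, s.site_id))
    if len(sense) == 1:
        return [dataclasses.replace(sense[0], rank="single")]
    ranks = ["proximal"] + ["internal"] * (len(sense) - 2) + ["distal"]
    return [dataclasses.replace(s, rank=r) for s, r in zip(sense, ranks)]
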