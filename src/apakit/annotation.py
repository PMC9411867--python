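"""Strand-aware 3'UTR construction, PAS motif scanning, and track overlap.

The polyadenylation signal (PAS, canonically AATAAA with common variant
ATTAAA) sits a few tens of nucleotides upstream of the cleavage site;
the UGUA element (TGTA on the DNA sense strand) is the binding motif of
cleavage factor I (CFI/NUDT21). Scanning the window upstream of each APA
site for these words is how site choice is annotated. Motifs are searched
on the transcript's sense strand, so minus-strand features must be (and
here are) reverse-complemented first.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .model import APAError, APASite, UTRRegion

DEFAULT_MOTIFS = ("AATAAA", "ATTAAA", "TGTA")
DEFAULT_WINDOW = 100

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence upstream of a cleavage site.

    ``offset`` is the distance in nt from the motif's first base to the
    cleavage site, measured upstream along the sense strand (a canonical
    PAS sits at offset ~10-40).
    """

    motif: str
    offset: int
    genomic_pos: int | None = None  # 1-based motif start, when known


def build_utr(utr_anchor: int, site: APASite) -> UTRRegion:
    """Construct a 3'UTR from its shared sense-strand start and one site.

    ``utr_anchor`` is the 0-based sense-strand 3'UTR start: on ``+`` the
    genomic start of the region, on ``-`` its genomic (exclusive) end.
    The UTR length is the strand-aware distance from the anchor to the
    cleavage site, so for two isoforms sharing the anchor,
    length_distal - length_proximal = |cleavage_distal - cleavage_proximal|.
    """
    if site.strand == "+":
        if not utr_anchor < site.cleavage_pos:
            raise APAError(
                f"cleavage at {site.cleavage_pos} is not downstream of the "
                f"3'UTR start {utr_anchor} on strand +"
            )
        return UTRRegion(transcript_id=site.transcript_id, chrom=site.chrom,
                         strand="+", start=utr_anchor, end=site.cleavage_pos)
    if not utr_anchor >= site.cleavage_pos:
        raise APAError(
            f"cleavage at {site.cleavage_pos} is not downstream of the "
            f"3'UTR end {utr_anchor} on strand -"
        )
    return UTRRegion(transcript_id=site.transcript_id, chrom=site.chrom,
                     strand="-", start=site.cleavage_pos - 1, end=utr_anchor)


def utr_anchor_from_length(site: APASite, utr_length: int) -> int:
    """Recover the shared 0-based sense-strand 3'UTR start from one
    isoform's cleavage site and its printed UTR length."""
    if utr_length < 1:
        raise APAError("UTR length must be >= 1")
    if site.strand == "+":
        return site.cleavage_pos - utr_length
    return site.cleavage_pos - 1 + utr_length


def scan_upstream_motifs(sense_sequence: str, window: int = DEFAULT_WINDOW,
                         motifs: Sequence[str] = DEFAULT_MOTIFS) -> list[MotifHit]:
    """Find motif words upstream of a cleavage site.

    ``sense_sequence`` is the sense-strand sequence ending at the cleavage
    site (minus-strand features must be reverse-complemented beforehand).
    All occurrences whose first base lies within ``window`` nt upstream of
    the 3' end are reported, overlapping ones included, with exact
    offsets. Sequences shorter than the window are scanned as-is.
    """
    seq = sense_sequence.upper()
    if re.search(r"[^ACGTN]", seq):
        bad = re.search(r"[^ACGTN]", seq).group()
        raise APAError(f"non-ACGTN character {bad!r} in sequence")
    L = len(seq)
    hits: list[MotifHit] = []
    for motif in motifs:
        m = motif.upper()
        start = 0
        while True:
            i = seq.find(m, start)
            if i == -1:
                break
            offset = L - i
            if offset <= window:
                hits.append(MotifHit(motif=m, offset=offset))
            start = i + 1  # overlapping occurrences all count
    hits.sort(key=lambda h: (h.offset, h.motif))
    return hits


def scan_site_motifs(fasta, site: APASite, window: int = DEFAULT_WINDOW,
                     motifs: Sequence[str] = DEFAULT_MOTIFS) -> list[MotifHit]:
    """Scan the genomic window upstream of a site using a pyfaidx FASTA.

    Extracts ``window`` nt ending at the cleavage site on the sense
    strand, reverse-complementing for minus-strand sites, and attaches
    1-based genomic start coordinates to each hit.
    """
    if site.strand == "+":
        gstart = max(0, site.cleavage_pos - window)  # 0-based
        raw = str(fasta[site.chrom][gstart:site.cleavage_pos])
        sense = raw
    else:
        gstart = site.cleavage_pos - 1
        raw = str(fasta[site.chrom][gstart:gstart + window])
        sense = reverse_complement(raw)
    hits = scan_upstream_motifs(sense, window=window, motifs=motifs)
    located = []
    for h in hits:
        if site.strand == "+":
            gpos = site.cleavage_pos - h.offset + 1
        else:
            gpos = site.cleavage_pos + h.offset - 1
        located.append(MotifHit(motif=h.motif, offset=h.offset, genomic_pos=gpos))
    return located


def overlap_tracks(regions: Sequence[UTRRegion | APASite],
                   track: Sequence, stranded: bool = False) -> list[list[str]]:
    """Names of track features overlapping each region.

    Both sides are treated as 0-based half-open intervals (sites become
    1-length intervals at the cleavage position); overlap requires an
    intersection of length >= 1, and matching strands when ``stranded``.
    """
    trees: dict[str, IntervalTree] = {}
    for feat in track:
        key = feat.chrom
        trees.setdefault(key, IntervalTree()).addi(feat.start, feat.end, feat)
    out: list[list[str]] = []
    for region in regions:
        if isinstance(region, APASite):
            chrom, start, end, strand = (region.chrom, region.cleavage_pos - 1,
                                         region.cleavage_pos, region.strand)
        else:
            chrom, start, end, strand = region.chrom, region.start, region.end, region.strand
        names = []
        for iv in trees.get(chrom, IntervalTree()).overlap(start, end):
            feat = iv.data
            if stranded and feat.strand != strand:
                continue
            names.append(feat.name)
        out.append(sorted(names))
    return out


_RANGE_RE = re.compile(r"^([^:]+):([0-9,]+)-([0-9,]+)$")


@dataclass
class QueryResult:
    """Matched sites plus any query keys that resolved to nothing."""

    sites: list[APASite]
    unmatched: list[str]

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]


def query(dataset, keys: str | Sequence[str],
          id_map: dict[str, str] | None = None) -> QueryResult:
    """Retrieve a dataset's sites by symbol, id, or genomic range.

    Each key may be a gene symbol, gene id, transcript id or site id
    (matched exactly, case-insensitively), or a range ``chrom:start-end``
    in 1-based inclusive coordinates (a site matches iff its cleavage
    position lies inside). An optional two-column id map translates
    foreign ids before matching. Keys that match nothing are reported in
    ``unmatched``, never silently dropped; list order is preserved in the
    returned union.
    """
    if isinstance(keys, str):
        keys = [keys]
    sites = dataset.sites if hasattr(dataset, "sites") else list(dataset)
    index: dict[str, list[APASite]] = {}
    for s in sites:
        for k in (s.gene_symbol, s.gene_id, s.transcript_id, s.site_id):
            index.setdefault(k.lower(), []).append(s)

    matched: list[APASite] = []
    seen: set[str] = set()
    unmatched: list[str] = []
    for key in keys:
        key = key.strip()
        lookup = (id_map or {}).get(key, key)
        m = _RANGE_RE.match(lookup)
        found: list[APASite] = []
        if m:
            chrom = m.group(1)
            try:
                lo = int(m.group(2).replace(",", ""))
                hi = int(m.group(3).replace(",", ""))
            except ValueError:
                raise APAError(
                    f"malformed range {lookup!r}; expected 'chrom:start-end'")
            if lo > hi:
                raise APAError(f"range {lookup!r} has start > end")
            found = [s for s in sites
                     if s.chrom == chrom and lo <= s.cleavage_pos <= hi]
        elif ":" in lookup:
            raise APAError(f"malformed range {lookup!r}; expected 'chrom:start-end'")
        else:
            found = index.get(lookup.lower(), [])
        if not found:
            unmatched.append(key)
        for s in found:
            if s.site_id not in seen:
                seen.add(s.site_id)
                matched.append(s)
    return QueryResult(sites=matched, unmatched=unmatched)
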