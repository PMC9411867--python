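"""Strand-aware 3'UTR length arithmetic and site queries.

Builds the bundled minus-strand worked-example gene (two APA isoforms of
a JAK1-like gene), recovers the shared 3'UTR start from the proximal
isoform's 107 bp UTR, and derives the distal isoform's UTR length.
"""

import io

from apakit import build_utr, jak1_like_dataset, query, utr_anchor_from_length, write_bed

ds = jak1_like_dataset()
by_rank = {s.rank: s for s in ds.sites}
proximal, distal = by_rank["proximal"], by_rank["distal"]

anchor = utr_anchor_from_length(proximal, utr_length=107)
distal_utr = build_utr(anchor, distal)
print(f"proximal site chr1:{proximal.cleavage_pos} (-)  UTR = 107 bp")
print(f"distal   site chr1:{distal.cleavage_pos} (-)  UTR = {distal_utr.length} bp")
# On the minus strand the lower coordinate is farther from the stop codon,
# so the 64833213 site yields the longer (1348 bp) 3'UTR.

res = query(ds, ["JAK1", "chr1:64833000-64834000", "NOPE"])
print(f"\nquery matched {len(res.sites)} site(s); unmatched keys: {res.unmatched}")

buf = io.StringIO()
write_bed(ds.sites, buf)
print("\nBED track of the two cleavage sites (0-based half-open):")
print(buf.getvalue(), end="")
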