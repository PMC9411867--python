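"""PAS/UGUA motif scanning upstream of cleavage sites and track overlap.

Constructs a sense-strand sequence with a canonical polyadenylation
signal (AATAAA) 40 nt upstream of the cleavage site and a CFI-binding
TGTA element, scans the 100 nt upstream window, and overlaps the
worked-example 3'UTRs with a small BED track.
"""

from apakit import jak1_like_dataset, overlap_tracks, scan_upstream_motifs
from apakit.io import BedInterval

# 100 nt of sense-strand sequence ending at the cleavage site
seq = ("G" * 20 + "TGTA" + "G" * 36 + "AATAAA" + "G" * 34)
hits = scan_upstream_motifs(seq, window=100, motifs=("AATAAA", "ATTAAA", "TGTA"))
print("motif hits (offset = nt from motif start to the cleavage site):")
for h in hits:
    print(f"  {h.motif} at {h.offset} nt upstream")
# The AATAAA at ~40 nt is the canonical PAS geometry; TGTA farther
# upstream marks a CFI/NUDT21 binding element.

ds = jak1_like_dataset()
track = [
    BedInterval("chr1", 64833200, 64833260, "PAS_DB_site", ".", "-"),
    BedInterval("chr1", 64900000, 64900100, "far_away", ".", "-"),
]
names = overlap_tracks(ds.utrs, track, stranded=True)
for utr, overlapping in zip(ds.utrs, names):
    print(f"3'UTR {utr.transcript_id} ({utr.length} bp) overlaps: "
          f"{overlapping or 'nothing'}")
# Only the long (distal) 3'UTR reaches the annotated PAS interval.
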