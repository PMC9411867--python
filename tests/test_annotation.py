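import numpy as np
import pytest

from apakit.annotation import (
    DEFAULT_MOTIFS,
    build_utr,
    overlap_tracks,
    query,
    scan_site_motifs,
    scan_upstream_motifs,
    utr_anchor_from_length,
)
from apakit.io import BedInterval
from apakit.model import APAError, APASite, UTRRegion

from conftest import brute_force_motifs, brute_force_overlaps


def site(pos, strand="+", chrom="chr1", tx="t1"):
    return APASite(site_id=f"s{pos}", gene_id="G", gene_symbol="G",
                   transcript_id=tx, chrom=chrom, strand=strand,
                   cleavage_pos=pos)


class TestBuildUtr:
    def test_plus_strand_length(self):
        utr = build_utr(100, site(200))
        assert (utr.start, utr.end, utr.length) == (100, 200, 100)

    def test_minus_strand_distal_from_proximal_length(self):
        # two minus-strand isoforms share the 3'UTR start; the proximal
        # one is 107 bp, so the distal length is 107 + inter-site distance
        proximal = site(64834454, "-")
        distal = site(64833213, "-")
        anchor = utr_anchor_from_length(proximal, 107)
        assert build_utr(anchor, proximal).length == 107
        assert build_utr(anchor, distal).length == 107 + (64834454 - 64833213)
        assert build_utr(anchor, distal).length == 1348

    def test_cleavage_upstream_of_anchor_rejected(self):
        with pytest.raises(APAError):
            build_utr(300, site(200))
        with pytest.raises(APAError):
            build_utr(100, site(200, "-"))

    @pytest.mark.parametrize("strand,p1,p2", [
        ("+", 5_000, 7_321), ("-", 7_321, 5_000)])
    def test_length_difference_identity(self, strand, p1, p2):
        anchor = 4_000 if strand == "+" else 8_000
        proximal, distal = site(p1, strand), site(p2, strand)
        lp = build_utr(anchor, proximal).length
        ld = build_utr(anchor, distal).length
        assert ld - lp == abs(p2 - p1)


class TestMotifScan:
    def test_pas_forty_nt_upstream(self):
        seq = "C" * 60 + "AATAAA" + "C" * 34  # starts 40 nt from the 3' end
        hits = scan_upstream_motifs(seq, window=100)
        assert [(h.motif, h.offset) for h in hits] == [("AATAAA", 40)]

    def test_no_motif_empty(self):
        assert scan_upstream_motifs("A" * 80) == []

    def test_overlapping_occurrences_all_reported(self):
        seq = "C" * 90 + "AATAAATAAA"
        hits = scan_upstream_motifs(seq, window=100, motifs=("AATAAA", "ATTAAA"))
        assert [(h.motif, h.offset) for h in hits] == \
            brute_force_motifs(seq, 100, ("AATAAA", "ATTAAA"))
        assert {h.offset for h in hits} == {6, 10}

    def test_window_excludes_far_upstream(self):
        seq = "AATAAA" + "C" * 200
        assert scan_upstream_motifs(seq, window=100) == []

    def test_non_acgtn_rejected(self):
        with pytest.raises(APAError, match="non-ACGTN"):
            scan_upstream_motifs("ACGTXACGT")

    def test_equals_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            seq = "".join(rng.choice(list("ACGT"), size=200))
            hits = scan_upstream_motifs(seq, window=100, motifs=DEFAULT_MOTIFS)
            assert [(h.motif, h.offset) for h in hits] == \
                brute_force_motifs(seq, 100, DEFAULT_MOTIFS)

    def test_fasta_scan_locates_genomic_positions(self, tmp_path):
        # plus strand: motif placed 40 nt upstream of cleavage at 100
        plus_seq = "C" * 60 + "AATAAA" + "C" * 34
        # minus strand: sense sequence is the reverse complement of the
        # genomic window starting at the cleavage position
        fa = tmp_path / "g.fa"
        minus_genomic = "".join({"A": "T", "T": "A", "C": "G", "G": "C"}[b]
                                for b in plus_seq[::-1])
        fa.write_text(f">chr1\n{plus_seq}\n>chr2\n{minus_genomic}\n")
        from pyfaidx import Fasta

        f = Fasta(str(fa))
        hits = scan_site_motifs(f, site(100, "+"), window=100)
        assert [(h.motif, h.offset, h.genomic_pos) for h in hits] == \
            [("AATAAA", 40, 61)]
        hits_m = scan_site_motifs(f, site(1, "-", chrom="chr2"), window=100)
        assert [(h.motif, h.offset) for h in hits_m] == [("AATAAA", 40)]
        assert hits_m[0].genomic_pos == 40


class TestOverlapTracks:
    def region(self, start, end, strand="+", chrom="chr1"):
        return UTRRegion(transcript_id=f"t{start}", chrom=chrom, strand=strand,
                         start=start, end=end)

    def test_basic_overlap(self):
        track = [BedInterval("chr1", 150, 160, "X")]
        assert overlap_tracks([self.region(100, 200)], track) == [["X"]]

    def test_half_open_boundary_no_overlap(self):
        track = [BedInterval("chr1", 200, 210, "X")]
        assert overlap_tracks([self.region(100, 200)], track) == [[]]

    def test_stranded_requires_matching_strand(self):
        track = [BedInterval("chr1", 150, 160, "X", ".", "-")]
        assert overlap_tracks([self.region(100, 200)], track, stranded=True) == [[]]
        assert overlap_tracks([self.region(100, 200, "-")], track,
                              stranded=True) == [["X"]]

    def test_site_is_single_base_interval(self):
        track = [BedInterval("chr1", 99, 100, "at99")]
        assert overlap_tracks([site(100)], track) == [["at99"]]
        assert overlap_tracks([site(101)], track) == [[]]

    def test_equals_brute_force_on_random_instances(self):
        rng = np.random.default_rng(13)
        chroms = ["chr1", "chr2"]
        regions = []
        raw = []
        for i in range(1000):
            start = int(rng.integers(0, 5000))
            end = start + int(rng.integers(1, 50))
            chrom = chroms[int(rng.integers(2))]
            strand = "+-"[int(rng.integers(2))]
            regions.append(UTRRegion(transcript_id=f"t{i}", chrom=chrom,
                                     strand=strand, start=start, end=end))
            raw.append((chrom, start, end, strand))
        track = []
        for i in range(1000):
            start = int(rng.integers(0, 5000))
            track.append(BedInterval(chroms[int(rng.integers(2))], start,
                                     start + int(rng.integers(1, 50)),
                                     f"f{i}", ".", "+-"[int(rng.integers(2))]))
        for stranded in (False, True):
            assert overlap_tracks(regions, track, stranded=stranded) == \
                brute_force_overlaps(raw, track, stranded=stranded)


class TestQuery:
    def test_symbol_query_case_insensitive(self, jak1_dataset):
        res = query(jak1_dataset, "jak1")
        assert len(res.sites) == 2
        assert res.unmatched == []

    def test_range_query_one_based_inclusive(self, jak1_dataset):
        res = query(jak1_dataset, "chr1:64833000-64835000")
        assert sorted(res.site_ids) == ["JAK1_1_D", "JAK1_2_P"]
        only_distal = query(jak1_dataset, "chr1:64833213-64833213")
        assert only_distal.site_ids == ["JAK1_1_D"]

    def test_gene_list_preserves_order_and_reports_unknown(self, jak1_dataset):
        res = query(jak1_dataset, ["NOPE", "JAK1"])
        assert res.unmatched == ["NOPE"]
        assert len(res.sites) == 2

    def test_malformed_range_rejected(self, jak1_dataset):
        with pytest.raises(APAError, match="range"):
            query(jak1_dataset, "chr1:abc-def")

    def test_id_map_translates_foreign_ids(self, jak1_dataset):
        res = query(jak1_dataset, "ENSG_JAK1", id_map={"ENSG_JAK1": "JAK1"})
        assert len(res.sites) == 2
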