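"""PTC geometry, 50-nt-rule classification and splice-site calls, checked
against a brute-force spliced-sequence walk."""

import numpy as np
import pytest

from aimseq.io import MutationRecord, TranscriptModel
from aimseq import nmd
from oracles import random_transcript, reflect_transcript, walk_ptc_features


def _snv(pos, category="nonsense", gene="G", ptc=None):
    return MutationRecord(
        sample_id="S1", gene=gene, chrom="chr1", pos=pos,
        ref_allele="C" if category != "frameshift" else "CA",
        alt_allele="T" if category != "frameshift" else "C",
        category=category, dna_ref=20, dna_alt=20, rna_ref=20, rna_alt=20,
        ptc_cds_pos=ptc,
    )


# single plus-strand exon [101,150] with CDS [111,140], and its minus mirror
PLUS_SINGLE = TranscriptModel("T+", "G", "chr1", "+", [(101, 150)], 111, 140)
MINUS_SINGLE = TranscriptModel("T-", "G", "chr1", "-", [(101, 150)], 140, 111)


class TestGenomicToCds:
    def test_plus_strand_cds_start(self):
        assert nmd.map_genomic_to_cds(PLUS_SINGLE, 111) == 1

    def test_minus_strand_mirror(self):
        assert nmd.map_genomic_to_cds(MINUS_SINGLE, 140) == 1

    def test_utr_returns_none(self):
        assert nmd.map_genomic_to_cds(PLUS_SINGLE, 105) is None

    def test_outside_span_raises(self):
        with pytest.raises(ValueError):
            nmd.map_genomic_to_cds(PLUS_SINGLE, 99)


def _three_exon_model():
    # exons 1-300, 401-700, 801-1100 (+); CDS genomic 51..1050
    return TranscriptModel("T3", "G", "chr1", "+",
                           [(1, 300), (401, 700), (801, 1100)], 51, 1050)


class TestAnnotatePtc:
    def test_sensitive_in_penultimate_exon(self):
        m = _three_exon_model()
        # last junction at spliced position 600; CDS starts at spliced 51.
        # PTC 60 nt upstream of the junction: spliced 540 -> CDS 490 (codon start)
        rec = _snv(pos=m.transcript_to_genomic(540))
        ann = nmd.annotate_ptc(rec, m)
        assert ann.region == "penultimate_ge50"
        assert ann.nmd_class == "sensitive"
        assert ann.dist_last_junction == 600 - (540 - (540 - 51) % 3)

    def test_last_exon_is_insensitive(self):
        m = _three_exon_model()
        rec = _snv(pos=m.transcript_to_genomic(700))  # spliced 700 is in exon 3
        ann = nmd.annotate_ptc(rec, m)
        assert ann.region == "last_exon" and ann.nmd_class == "insensitive"
        assert ann.dist_last_junction < 0
        assert ann.dist_downstream_junction is None

    def test_exactly_50nt_boundary_sensitive_by_default(self):
        # CDS start shifted to genomic 52 so that spliced 550 (exactly 50 nt
        # upstream of the last junction at 600) is a codon start
        m = TranscriptModel("T3b", "G", "chr1", "+",
                            [(1, 300), (401, 700), (801, 1100)], 52, 1050)
        rec = _snv(pos=m.transcript_to_genomic(550))
        ann = nmd.annotate_ptc(rec, m)
        assert ann.dist_last_junction == 50
        assert ann.region == "penultimate_ge50" and ann.nmd_class == "sensitive"
        strict = nmd.annotate_ptc(rec, m, boundary_inclusive=False)
        assert strict.nmd_class == "insensitive"

    def test_frameshift_requires_ptc_or_sequence(self):
        m = _three_exon_model()
        rec = _snv(pos=m.transcript_to_genomic(100), category="frameshift")
        with pytest.raises(nmd.AnnotationError):
            nmd.annotate_ptc(rec, m)
        ann = nmd.annotate_ptc(_snv(pos=m.transcript_to_genomic(100),
                                    category="frameshift", ptc=200), m)
        assert ann.ptc_cds_pos == 200

    def test_frameshift_retranslation_fallback(self):
        # 2-exon plus transcript, CDS covers the whole spliced sequence; a 1-nt
        # deletion at CDS 5 brings a TAA into frame at codon 2 (CDS nt 4)
        # deleting CDS nt 6 reads seq[3], seq[4], seq[6] = "TAA" at codon 2
        seq = "ATGTACA" + "GCT" * 7 + "GA"
        m = TranscriptModel("T", "G", "chr1", "+", [(1, 15), (101, 115)], 1, 115,
                            cds_sequence=seq)
        rec = _snv(pos=5, category="frameshift")
        ann = nmd.annotate_ptc(rec, m, allow_retranslation=True)
        assert ann.ptc_cds_pos == 4

    def test_ptc_outside_cds_rejected(self):
        m = _three_exon_model()
        rec = _snv(pos=10, category="nonsense")  # 5'UTR (CDS starts at 51)
        with pytest.raises(nmd.AnnotationError):
            nmd.annotate_ptc(rec, m)

    def test_bruteforce_oracle_over_random_transcripts(self):
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            m = random_transcript(rng)
            ptc_cds = int(rng.integers(1, m.cds_length + 1))
            ptc_cds -= (ptc_cds - 1) % 3
            tpos = m.cds_transcript_start + ptc_cds - 1
            rec = _snv(pos=m.transcript_to_genomic(tpos))
            ann = nmd.annotate_ptc(rec, m)
            oracle = walk_ptc_features(m, ptc_cds)
            assert ann.exon_index == oracle["exon_index"]
            assert ann.dist_last_junction == oracle["dist_last_junction"]
            assert ann.dist_start_codon == oracle["dist_start_codon"]
            assert ann.dist_downstream_junction == oracle["dist_downstream_junction"]

    def test_strand_reflection_invariance(self):
        rng = np.random.default_rng(999)
        for _ in range(200):
            m = random_transcript(rng)
            pivot = int(rng.integers(200_000, 400_000))
            refl = reflect_transcript(m, pivot)
            ptc_cds = int(rng.integers(1, m.cds_length + 1))
            ptc_cds -= (ptc_cds - 1) % 3
            tpos = m.cds_transcript_start + ptc_cds - 1
            a1 = nmd.annotate_ptc(_snv(pos=m.transcript_to_genomic(tpos)), m)
            a2 = nmd.annotate_ptc(
                _snv(pos=refl.transcript_to_genomic(tpos)), refl)
            for f in ("ptc_cds_pos", "exon_index", "dist_last_junction",
                      "dist_start_codon", "dist_downstream_junction",
                      "region", "nmd_class"):
                assert getattr(a1, f) == getattr(a2, f)

    def test_region_partition_and_determinism(self):
        rng = np.random.default_rng(55)
        for _ in range(300):
            m = random_transcript(rng)
            ptc_cds = int(rng.integers(1, m.cds_length + 1))
            ptc_cds -= (ptc_cds - 1) % 3
            rec = _snv(pos=m.transcript_to_genomic(m.cds_transcript_start + ptc_cds - 1))
            ann = nmd.annotate_ptc(rec, m)
            assert ann.region in nmd.REGIONS
            assert (ann.region == "last_exon") == (ann.exon_index == len(m.exons))
            if ann.region == "last_exon":
                assert ann.nmd_class == "insensitive"
            else:
                assert ann.nmd_class == (
                    "sensitive" if ann.dist_last_junction >= 50 else "insensitive")


class TestSpliceSite:
    # plus strand, exon 1 ends at 150, exon 2 starts at 201
    M = TranscriptModel("T", "G", "chr1", "+", [(101, 150), (201, 260)], 111, 250)

    def test_donor_plus_one(self):
        call = nmd.classify_splice_site(_snv(151, "splice_site"), self.M)
        assert (call.side, call.offset, call.canonical_ref) == ("donor_5prime", 1, "G")

    def test_donor_plus_two(self):
        call = nmd.classify_splice_site(_snv(152, "splice_site"), self.M)
        assert (call.side, call.offset, call.canonical_ref) == ("donor_5prime", 2, "T")

    def test_acceptor_minus_one(self):
        call = nmd.classify_splice_site(_snv(200, "splice_site"), self.M)
        assert (call.side, call.offset, call.canonical_ref) == ("acceptor_3prime", -1, "G")

    def test_acceptor_minus_two(self):
        call = nmd.classify_splice_site(_snv(199, "splice_site"), self.M)
        assert (call.side, call.offset, call.canonical_ref) == ("acceptor_3prime", -2, "A")

    def test_minus_strand_mirror(self):
        refl = reflect_transcript(self.M, 1000)
        # donor +1 on the mirrored model is genomic 1000 - 151
        call = nmd.classify_splice_site(_snv(1000 - 151, "splice_site"), refl)
        assert (call.side, call.offset, call.canonical_ref) == ("donor_5prime", 1, "G")

    def test_deep_intronic_rejected(self):
        with pytest.raises(nmd.AnnotationError):
            nmd.classify_splice_site(_snv(170, "splice_site"), self.M)


class TestFirstExonFeatures:
    def test_basic_table(self):
        m = _three_exon_model()
        anns = [
            nmd.annotate_ptc(_snv(pos=m.transcript_to_genomic(m.cds_transcript_start + 29)), m),
            nmd.annotate_ptc(_snv(pos=m.transcript_to_genomic(700)), m),
        ]
        table = nmd.first_exon_features(anns)
        assert bool(table.iloc[0]["in_first_exon"]) is True
        assert table.iloc[0]["dist_start_codon"] == 27  # codon start of CDS 30 is 28
        assert bool(table.iloc[1]["in_first_exon"]) is False

    def test_single_exon_transcript_is_first_and_last(self):
        rec = _snv(pos=120)
        ann = nmd.annotate_ptc(rec, PLUS_SINGLE)
        assert ann.exon_index == 1 and ann.region == "last_exon"
        table = nmd.first_exon_features([ann])
        assert bool(table.iloc[0]["in_first_exon"]) is True
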