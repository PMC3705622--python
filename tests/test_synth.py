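"""Generator tests: ancestor geometry, planting, truth-table consistency,
transcription, in-silico PCR, clone sampling, and determinism."""

import numpy as np
import pytest

from ervkit import synth
from ervkit.cli import default_transcript_program
from ervkit.core import PrimerPair, revcomp
from ervkit.splice import TYPE2_SEGMENT_LEN


class TestBuildAncestor:
    def test_geometry(self, ancestor):
        assert 9400 <= len(ancestor.seq) <= 9500
        s, e = ancestor.type2_segment
        assert e - s == TYPE2_SEGMENT_LEN
        assert ancestor.provirus_type == "II"

    def test_ltrs_identical(self, ancestor):
        l5 = ancestor.seq[ancestor.ltr5[0] : ancestor.ltr5[1]]
        l3 = ancestor.seq[ancestor.ltr3[0] : ancestor.ltr3[1]]
        assert l5 == l3
        assert len(l5) == 968

    def test_canonical_dinucleotides(self, ancestor):
        c5, c3 = ancestor.canonical_5ss, ancestor.canonical_3ss
        assert ancestor.seq[c5 : c5 + 2] == "GT"
        assert ancestor.seq[c3 - 2 : c3] == "AG"

    def test_deterministic(self):
        a = synth.build_ancestor(synth.SimConfig(seed=3))
        b = synth.build_ancestor(synth.SimConfig(seed=3))
        c = synth.build_ancestor(synth.SimConfig(seed=4))
        assert a.seq == b.seq
        assert a.seq != c.seq


class TestPlantLoci:
    def test_fragment_counts_vs_truth(self, small_sim):
        ltr_rows = [f for f in small_sim.fragments if f.rep_name == "LTR5_Hs"]
        int_rows = [f for f in small_sim.fragments if f.rep_name == "HERVK-int"]
        n_prov = sum(1 for lt in small_sim.truth.loci if lt.kind == "provirus")
        n_solo = sum(1 for lt in small_sim.truth.loci if lt.kind == "solo_ltr")
        assert len(ltr_rows) >= 2 * n_prov + n_solo
        assert len(int_rows) >= n_prov

    def test_type1_internal_reported_as_two_rows(self, small_sim):
        for lt in small_sim.truth.loci:
            int_segs = [s for s in lt.mask_segments if s[2] == "int"]
            if lt.provirus_type == "I":
                assert len(int_segs) >= 2
                # split rows are adjacent (consensus jump, no genomic gap)
                assert int_segs[0][1] == int_segs[1][0]

    def test_solo_ltr_flanked_by_tsd(self, small_sim):
        genome = small_sim.genome.seq
        for lt in small_sim.truth.loci:
            iv = lt.interval
            left = genome[iv.start - len(lt.tsd) : iv.start]
            right = genome[iv.end : iv.end + len(lt.tsd)]
            assert left == lt.tsd and right == lt.tsd

    def test_genome_carries_locus_seq(self, small_sim):
        genome = small_sim.genome.seq
        for lt in small_sim.truth.loci:
            iv = lt.interval
            planted = genome[iv.start : iv.end]
            expected = lt.seq if iv.strand == "+" else revcomp(lt.seq)
            assert planted == expected

    def test_zero_divergence_identical_paralogs(self):
        config = synth.SimConfig(seed=2, pairwise_divergence=0.0, n_proviruses=3, n_solo_ltrs=2)
        sim = synth.plant_loci(config)
        prov_seqs = {lt.seq for lt in sim.truth.loci if lt.kind == "provirus" and lt.provirus_type == "II"}
        solo_seqs = {lt.seq for lt in sim.truth.loci if lt.kind == "solo_ltr"}
        assert len(prov_seqs) == 1
        assert len(solo_seqs) == 1

    def test_pairwise_divergence_near_target(self):
        config = synth.SimConfig(seed=8, pairwise_divergence=0.01, n_proviruses=4, n_solo_ltrs=0)
        sim = synth.plant_loci(config)
        type2 = [lt.seq for lt in sim.truth.loci if lt.provirus_type == "II"]
        a, b = type2[0], type2[1]
        diffs = sum(1 for x, y in zip(a, b) if x != y)
        d = diffs / len(a)
        assert 0.005 < d < 0.016  # ~1% expected

    def test_too_small_genome_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            synth.plant_loci(synth.SimConfig(seed=1, genome_len=50_000))

    def test_deterministic(self):
        a = synth.plant_loci(synth.SimConfig(seed=6, genome_len=250_000, n_proviruses=3, n_solo_ltrs=3))
        b = synth.plant_loci(synth.SimConfig(seed=6, genome_len=250_000, n_proviruses=3, n_solo_ltrs=3))
        assert a.genome.seq == b.genome.seq
        assert [f.interval for f in a.fragments] == [f.interval for f in b.fragments]


class TestTranscribe:
    def test_unspliced_has_two_r_copies(self, small_sim):
        for tx in small_sim.truth.transcripts:
            lt = small_sim.truth.locus(tx.locus_id)
            if lt.kind != "provirus" or tx.spliced:
                continue
            lm = lt.landmarks
            r_seq = lt.seq[lm.r5[0] : lm.r5[1]]
            seq = tx.seq if tx.strand == "+" else revcomp(tx.seq)
            assert seq.count(r_seq) == 2

    def test_solo_transcript_one_r_copy(self, small_sim):
        for tx in small_sim.truth.transcripts:
            lt = small_sim.truth.locus(tx.locus_id)
            if lt.kind != "solo_ltr":
                continue
            r_seq = lt.seq[synth.U3_LEN : synth.U3_LEN + synth.R_LEN]
            seq = tx.seq if tx.strand == "+" else revcomp(tx.seq)
            assert seq.count(r_seq) == 1

    def test_spliced_excises_programmed_intron(self, small_sim):
        for tx in small_sim.truth.transcripts:
            if not tx.spliced:
                continue
            lt = small_sim.truth.locus(tx.locus_id)
            lm = lt.landmarks
            unspliced_len = lm.r3[1] - lm.r5[0]
            intron_len = (lm.c3ss + tx.acceptor_offset) - (lm.c5ss + tx.donor_offset)
            assert len(tx.seq) == unspliced_len - intron_len

    def test_antisense_is_revcomp(self, small_sim):
        tx_by_locus = {}
        for tx in small_sim.truth.transcripts:
            tx_by_locus.setdefault((tx.locus_id, tx.spliced), tx)
        minus = [t for t in small_sim.truth.transcripts if t.strand == "-"]
        assert minus, "program should contain antisense transcripts"
        for tx in minus:
            lt = small_sim.truth.locus(tx.locus_id)
            if lt.kind == "provirus" and not tx.spliced:
                lm = lt.landmarks
                assert tx.seq == revcomp(lt.seq[lm.r5[0] : lm.r3[1]])


class TestInSilicoPcr:
    def test_type2_minus_type1_product_is_292(self, ancestor):
        primers = synth.design_primers(ancestor)["unspliced"]
        type1_seq = (
            ancestor.seq[: ancestor.type2_segment[0]] + ancestor.seq[ancestor.type2_segment[1] :]
        )
        t2 = synth.TranscriptTruth("t2", "A", "+", False, 0, 0, 1.0, ancestor.seq)
        t1 = synth.TranscriptTruth("t1", "B", "+", False, 0, 0, 1.0, type1_seq)
        p2 = synth.in_silico_pcr([t2], primers)
        p1 = synth.in_silico_pcr([t1], primers)
        assert len(p2) == 1 and len(p1) == 1
        assert len(p2[0].seq) - len(p1[0].seq) == 292

    def test_mismatch_budget(self, ancestor):
        primers = synth.design_primers(ancestor)["env-1"]
        fwd = list(primers.fwd)
        for i in (2, 8, 14):  # 3 mismatches
            fwd[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[fwd[i]]
        bad = PrimerPair("bad", "".join(fwd), primers.rev)
        tx = synth.TranscriptTruth("t", "A", "+", False, 0, 0, 1.0, ancestor.seq)
        assert synth.in_silico_pcr([tx], bad, max_mismatch=1) == []
        assert len(synth.in_silico_pcr([tx], primers, max_mismatch=1)) == 1

    def test_intron_crossing_pair(self, ancestor):
        # the 1x pair yields no product on unspliced RNA (too long) but one
        # on the spliced transcript
        primers = synth.design_primers(ancestor)["1x-env"]
        c5, c3 = ancestor.canonical_5ss, ancestor.canonical_3ss
        spliced_seq = ancestor.seq[:c5] + ancestor.seq[c3:]
        unspliced = synth.TranscriptTruth("u", "A", "+", False, 0, 0, 1.0, ancestor.seq)
        spliced = synth.TranscriptTruth("s", "A", "+", True, 0, 0, 1.0, spliced_seq)
        assert synth.in_silico_pcr([unspliced], primers) == []
        assert len(synth.in_silico_pcr([spliced], primers)) == 1

    def test_antisense_template_detected(self, ancestor):
        primers = synth.design_primers(ancestor)["env-1"]
        tx = synth.TranscriptTruth("t", "A", "-", False, 0, 0, 1.0, revcomp(ancestor.seq))
        products = synth.in_silico_pcr([tx], primers)
        assert len(products) == 1
        assert products[0].strand == "-"


class TestSampleClones:
    def _pool(self, weights):
        return [
            synth.Amplicon(f"t{i}", f"L{i}", 0, 60, "ACGT" * 15, w)
            for i, w in enumerate(weights)
        ]

    def test_seeded_identical(self):
        pool = self._pool([1, 2, 3])
        a = synth.sample_clones(pool, 20, seed=5)
        b = synth.sample_clones(pool, 20, seed=5)
        assert [c.locus_id for c in a] == [c.locus_id for c in b]

    def test_proportions_near_weights(self):
        pool = self._pool([90, 10])
        clones = synth.sample_clones(pool, 1000, seed=11)
        frac = sum(1 for c in clones if c.locus_id == "L0") / 1000
        assert abs(frac - 0.90) <= 0.03  # 3 sigma of binomial(1000, .9)

    def test_single_source(self):
        clones = synth.sample_clones(self._pool([1.0]), 7, seed=0)
        assert len(clones) == 7
        assert {c.locus_id for c in clones} == {"L0"}

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            synth.sample_clones([], 5, seed=0)


class TestTruthTable:
    def test_json_serializable(self, small_sim):
        payload = small_sim.truth.to_json()
        import json

        data = json.loads(payload)
        assert len(data["loci"]) == len(small_sim.truth.loci)
        assert len(data["transcripts"]) == len(small_sim.truth.transcripts)
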