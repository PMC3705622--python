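"""Splice-junction inference tests: planted-intron construction and
recovery, donor/acceptor classification, type I/II detection, amplicon
prediction, and the seeded noise-robustness trials."""

import numpy as np
import pytest

from ervkit import synth
from ervkit.core import revcomp
from ervkit.splice import (
    ProvirusModel,
    SpliceJunction,
    TYPE2_SEGMENT_LEN,
    classify_sites,
    detect_type,
    find_deletions,
    find_junction,
    predict_amplicon_sizes,
)


def _plant_junction(model: ProvirusModel, donor: int, acceptor: int) -> ProvirusModel:
    """Copy of the model with GT..AG planted at a trial junction."""
    seq = model.seq
    seq = seq[:donor] + "GT" + seq[donor + 2 :]
    seq = seq[: acceptor - 2] + "AG" + seq[acceptor:]
    return ProvirusModel(
        seq=seq,
        ltr5=model.ltr5,
        ltr3=model.ltr3,
        canonical_5ss=model.canonical_5ss,
        canonical_3ss=model.canonical_3ss,
        type2_segment=model.type2_segment,
        provirus_type=model.provirus_type,
    )


def _spliced_cdna(model: ProvirusModel, donor: int, acceptor: int, flank: int) -> str:
    return model.seq[donor - flank : donor] + model.seq[acceptor : acceptor + flank]


def _mutate(rng, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    for i in np.nonzero(rng.random(len(arr)) < rate)[0]:
        options = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = options[rng.integers(0, 3)]
    return arr.tobytes().decode()


class TestFindJunction:
    def test_contiguous_cdna_returns_none(self, ancestor):
        cdna = ancestor.seq[2000:2400]
        assert find_junction(cdna, ancestor) is None

    def test_canonical_intron_excised(self, ancestor):
        c5, c3 = ancestor.canonical_5ss, ancestor.canonical_3ss
        cdna = ancestor.seq[c5 - 150 : c5] + ancestor.seq[c3 : c3 + 150]
        j = find_junction(cdna, ancestor)
        assert j is not None
        assert (j.donor_offset, j.acceptor_offset) == (0, 0)
        assert j.ss_class == "canonical"
        assert j.donor_dinuc == "GT" and j.acceptor_dinuc == "AG"

    def test_alt_donor_435_acceptor_6(self, ancestor):
        # planted alternative junction: +435 donor / +6 acceptor
        c5, c3 = ancestor.canonical_5ss, ancestor.canonical_3ss
        cdna = _spliced_cdna(ancestor, c5 + 435, c3 + 6, 200)
        j = find_junction(cdna, ancestor)
        assert j is not None
        assert (j.donor_offset, j.acceptor_offset) == (435, 6)
        assert j.ss_class == "alt_minor"

    def test_short_cdna_rejected(self, ancestor):
        with pytest.raises(ValueError):
            find_junction("ACGT" * 10, ancestor)

    def test_orientation_consistency(self, ancestor):
        c5, c3 = ancestor.canonical_5ss, ancestor.canonical_3ss
        cdna = _spliced_cdna(ancestor, c5, c3, 120)
        j_fwd = find_junction(cdna, ancestor)
        n = len(ancestor.seq)
        mirrored = ProvirusModel(
            seq=revcomp(ancestor.seq),
            ltr5=(n - ancestor.ltr3[1], n - ancestor.ltr3[0]),
            ltr3=(n - ancestor.ltr5[1], n - ancestor.ltr5[0]),
            canonical_5ss=n - c3,
            canonical_3ss=n - c5,
            type2_segment=None,
            provirus_type="I",
        )
        j_rev = find_junction(revcomp(cdna), mirrored)
        assert j_rev is not None
        assert j_rev.donor_pos == n - j_fwd.acceptor_pos
        assert j_rev.acceptor_pos == n - j_fwd.donor_pos

    def test_clean_recovery_planted_introns(self, ancestor):
        # flanks >= 25 nt, mutation-free: recovery is exact
        rng = np.random.default_rng(5150)
        c5, c3 = ancestor.canonical_5ss, ancestor.canonical_3ss
        for _ in range(50):
            d = c5 + int(rng.integers(-300, 301))
            a = c3 + int(rng.integers(-300, 301))
            model = _plant_junction(ancestor, d, a)
            f1 = int(rng.integers(25, 200))
            f2 = max(int(rng.integers(25, 200)), 60 - f1)
            cdna = model.seq[d - f1 : d] + model.seq[a : a + f2]
            j = find_junction(cdna, model, search_window=400)
            assert j is not None, (d - c5, a - c3, f1, f2)
            assert (j.donor_pos, j.acceptor_pos) == (d, a)

    def test_noise_recovery_rate(self, ancestor):
        # 1% substitution noise: offsets exact in >= 95% of 200 seeded trials
        rng = np.random.default_rng(777)
        c5, c3 = ancestor.canonical_5ss, ancestor.canonical_3ss
        exact = 0
        n_trials = 200
        for _ in range(n_trials):
            d = c5 + int(rng.integers(-300, 301))
            a = c3 + int(rng.integers(-300, 301))
            model = _plant_junction(ancestor, d, a)
            cdna = _mutate(rng, _spliced_cdna(model, d, a, 150), 0.01)
            j = find_junction(cdna, model, search_window=400)
            if j is not None and (j.donor_pos, j.acceptor_pos) == (d, a):
                exact += 1
        assert exact / n_trials >= 0.95


class TestClassifySites:
    def _junction(self, model, d, a):
        return SpliceJunction(
            donor_pos=d,
            acceptor_pos=a,
            donor_offset=d - model.canonical_5ss,
            acceptor_offset=a - model.canonical_3ss,
            donor_dinuc=model.seq[d : d + 2],
            acceptor_dinuc=model.seq[a - 2 : a],
            ss_class="",
            matches=0,
        )

    def test_canonical(self, ancestor):
        j = self._junction(ancestor, ancestor.canonical_5ss, ancestor.canonical_3ss)
        assert classify_sites(ancestor, j) == "canonical"

    def test_alt_major_gt_donor(self, ancestor):
        model = _plant_junction(ancestor, ancestor.canonical_5ss + 50, ancestor.canonical_3ss)
        j = self._junction(model, model.canonical_5ss + 50, model.canonical_3ss)
        assert classify_sites(model, j) == "alt_major"

    def test_alt_minor_donor(self, ancestor):
        d = ancestor.canonical_5ss + synth.ALT_DONOR_OFFSET
        assert ancestor.seq[d : d + 6] == "ATATCC"
        j = self._junction(ancestor, d, ancestor.canonical_3ss + 6)
        assert classify_sites(ancestor, j) == "alt_minor"

    def test_non_canonical(self, ancestor):
        # find a shifted donor that is neither GT nor minor-consensus
        c5 = ancestor.canonical_5ss
        for off in range(20, 400):
            ctx = ancestor.seq[c5 + off : c5 + off + 6]
            import re

            if ctx[:2] != "GT" and not re.fullmatch("[GA]TATCC", ctx):
                j = self._junction(ancestor, c5 + off, ancestor.canonical_3ss)
                assert classify_sites(ancestor, j) == "non_canonical"
                return
        pytest.fail("no non-canonical context found")


class TestDetectType:
    def test_self_is_type2(self, ancestor):
        ptype, dlen, _ = detect_type(ancestor.seq, ancestor)
        assert ptype == "II" and dlen == 0

    def test_excised_segment_is_type1(self, ancestor):
        s, e = ancestor.type2_segment
        type1_seq = ancestor.seq[:s] + ancestor.seq[e:]
        ptype, dlen, locus = detect_type(type1_seq, ancestor)
        assert ptype == "I"
        assert dlen == TYPE2_SEGMENT_LEN
        assert locus[0] < e and locus[1] > s

    def test_mutated_type1_locus(self, ancestor):
        cfg = synth.SimConfig(seed=5)
        rng = np.random.default_rng(5)
        locus = synth._make_locus(rng, ancestor, "x", "provirus", "I", 0.01)
        ptype, dlen, _ = detect_type(locus.seq, ancestor)
        assert ptype == "I" and dlen == TYPE2_SEGMENT_LEN

    def test_small_deletion_not_type1(self, ancestor):
        s, _ = ancestor.type2_segment
        small_del = ancestor.seq[: s + 50] + ancestor.seq[s + 90 :]  # 40 bp
        ptype, dlen, _ = detect_type(small_del, ancestor)
        assert ptype == "II"

    def test_find_deletions_planted_164(self, ancestor):
        # K60-like: an extra 164-bp deletion in the env region
        c3 = ancestor.canonical_3ss
        pos = c3 + 500
        mutant = ancestor.seq[:pos] + ancestor.seq[pos + 164 :]
        dels = find_deletions(mutant[c3 : c3 + 1200], ancestor.seq[c3 : c3 + 1200], min_len=100)
        assert len(dels) == 1
        assert dels[0][1] - dels[0][0] == 164


class TestPredictAmpliconSizes:
    def test_type2_minus_type1_is_292(self, ancestor):
        s, e = ancestor.type2_segment
        fwd = ancestor.seq[s - 300 : s - 280]
        rev = revcomp(ancestor.seq[e + 230 : e + 250])
        type1_seq = ancestor.seq[:s] + ancestor.seq[e:]
        p2 = predict_amplicon_sizes(ancestor.seq, fwd, rev)
        p1 = predict_amplicon_sizes(type1_seq, fwd, rev)
        assert len(p2) == 1 and len(p1) == 1
        assert p2[0] - p1[0] == TYPE2_SEGMENT_LEN

    def test_absent_primer_no_product(self, ancestor):
        fwd = "A" * 20
        rev = revcomp(ancestor.seq[5000:5020])
        assert predict_amplicon_sizes(ancestor.seq, fwd, rev, max_mismatch=0) == []

    def test_spliced_product_shorter_by_intron(self, ancestor):
        c5, c3 = ancestor.canonical_5ss, ancestor.canonical_3ss
        fwd = ancestor.seq[c5 - 60 : c5 - 40]
        rev = revcomp(ancestor.seq[c3 + 40 : c3 + 60])
        spliced = ancestor.seq[:c5] + ancestor.seq[c3:]
        genomic = predict_amplicon_sizes(ancestor.seq, fwd, rev, max_len=10_000)
        on_spliced = predict_amplicon_sizes(spliced, fwd, rev, max_len=10_000)
        assert genomic[0] - on_spliced[0] == c3 - c5
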