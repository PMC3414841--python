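"""Indel architecture: repeat vs microhomology classification and statistics."""

import numpy as np
import pytest

from mutforge.catalog import IndelRecord, ReferenceGenome, reverse_complement
from mutforge.indels import (
    IndelClassification,
    classify_all,
    classify_indel,
    expected_microhomology,
    group_comparison,
    ks_two_sample,
)


def _del(chrom, pos, seq, sample="s"):
    return IndelRecord(sample, chrom, pos, "deletion", seq, len(seq))


class TestClassifyIndel:
    def test_tandem_repeat_deletion(self):
        #                 123456789012345678
        g = ReferenceGenome({"c": "AATTGCAGCAGCAGTTAA"})
        # delete the middle CAG (1-based 9-11); pos = base 5' of event = 8
        rec = _del("c", 8, "CAG")
        cls = classify_indel(rec, g)
        assert cls.klass == "repeat"
        assert cls.repeat_unit == "CAG"
        assert cls.adjacent_repeat_copies == 2

    def test_microhomology_prefix_match(self):
        # deletion ATGCC followed in the reference by ATG...
        g = ReferenceGenome({"c": "TTTTTTTTATGCCATGAAAATTTTGGGG"})
        rec = _del("c", 8, "ATGCC")  # deletes 9..13, 3' flank starts ATG
        cls = classify_indel(rec, g)
        assert cls.klass == "microhomology"
        assert cls.mh_length == 3

    def test_suffix_match_counts_too(self):
        # 5' flank ends with GG; deleted seq ends with GG; no 3' identity
        g = ReferenceGenome({"c": "AAATTCCGGTAGGCTACTCAATTCAATT"})
        rec = _del("c", 9, "TAGG")  # deletes 10..13 = TAGG, left flank ...CCGG
        cls = classify_indel(rec, g)
        assert cls.klass == "microhomology"
        assert cls.mh_length == 2

    def test_featureless_deletion_is_none(self):
        g = ReferenceGenome({"c": "AAAAAACGTGCAATTTTTT"})
        rec = _del("c", 6, "CGTG")  # 3' flank CAAT, 5' flank AAAAAA
        cls = classify_indel(rec, g)
        assert cls.klass == "none"
        assert cls.mh_length <= 1

    def test_random_fixtures_match_brute_force_oracle(self):
        """1,000 random deletions on a random genome: classification agrees
        with an independent brute-force string scan."""
        rng = np.random.default_rng(61)
        seq = "".join(rng.choice(list("ACGT"), size=30_000))
        g = ReferenceGenome({"c": seq})

        def oracle(pos, L, mh_min=2, max_unit=6):
            s = seq[pos : pos + L]  # deleted bases, 0-based slice
            left = seq[max(pos - 50, 0) : pos]
            right = seq[pos + L : pos + L + 50]
            # repeat first
            for u in range(1, min(max_unit, L) + 1):
                if L % u == 0 and s == s[:u] * (L // u):
                    if right.startswith(s[:u]) or left.endswith(s[:u]):
                        return "repeat"
                    break  # smallest tiling unit is decisive
            pre = 0
            for a, b in zip(s, right):
                if a != b:
                    break
                pre += 1
            suf = 0
            for a, b in zip(s[::-1], left[::-1]):
                if a != b:
                    break
                suf += 1
            return "microhomology" if max(pre, suf) >= mh_min else "none"

        for _ in range(1000):
            L = int(rng.integers(1, 20))
            pos = int(rng.integers(60, len(seq) - 80))
            got = classify_indel(_del("c", pos, seq[pos : pos + L]), g)
            assert got.klass == oracle(pos, L)

    def test_reverse_complement_invariance(self):
        """Classifying the same deletion on the reverse-complemented locus
        yields the same class and microhomology length."""
        rng = np.random.default_rng(62)
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        g_fwd = ReferenceGenome({"c": seq})
        g_rev = ReferenceGenome({"c": reverse_complement(seq)})
        n = len(seq)
        for _ in range(300):
            L = int(rng.integers(1, 15))
            pos = int(rng.integers(60, n - 80))
            fwd = classify_indel(_del("c", pos, seq[pos : pos + L]), g_fwd)
            # deleted bases occupy 1-based pos+1..pos+L; on the reverse
            # strand they occupy n-pos-L+1..n-pos, anchored at n-pos-L
            rev_pos = n - pos - L
            rev_seq = reverse_complement(seq[pos : pos + L])
            rev = classify_indel(_del("c", rev_pos, rev_seq), g_rev)
            assert fwd.klass == rev.klass
            assert fwd.mh_length == rev.mh_length

    def test_insertion_repeat_only(self):
        g = ReferenceGenome({"c": "AAATTCAGCAGTTTTAAA"})
        ins = IndelRecord("s", "c", 11, "insertion", "CAG", 3)  # after ...CAG
        assert classify_indel(ins, g).klass == "repeat"
        ins2 = IndelRecord("s", "c", 14, "insertion", "GGC", 3)
        assert classify_indel(ins2, g).klass == "none"

    def test_generated_truth_recovered(self, small_sg):
        from mutforge.catalog import MutationCatalog
        from mutforge.synthetic import IndelSpec, SyntheticTruth, inject_indels

        truth = SyntheticTruth()
        cat = inject_indels(
            MutationCatalog("s"), small_sg, IndelSpec(400, 300, 200), seed=63,
            truth=truth,
        )
        cls = classify_all(cat.indels, small_sg.genome)
        agree = sum(
            1
            for c in cls
            if truth.indel_classes[("s", c.record.chrom, c.record.pos)] == c.klass
        )
        assert agree / len(cls) >= 0.95


class TestKs:
    def test_identical_samples(self):
        res = ks_two_sample([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_disjoint_supports(self):
        res = ks_two_sample([1, 2], [10, 11])
        assert res.statistic == 1.0

    def test_statistic_matches_ecdf_oracle(self):
        rng = np.random.default_rng(64)
        a = rng.integers(1, 30, size=80)
        b = rng.integers(5, 40, size=60)
        res = ks_two_sample(a, b)
        grid = np.unique(np.concatenate([a, b]))
        d = max(
            abs((a <= x).mean() - (b <= x).mean()) for x in grid
        )
        assert res.statistic == pytest.approx(d, abs=1e-12)

    def test_empty_sample_na(self):
        res = ks_two_sample([], [1, 2])
        assert np.isnan(res.statistic)

    def test_repeat_vs_mh_lengths_differ_on_generated_data(self, small_sg):
        from mutforge.catalog import MutationCatalog
        from mutforge.synthetic import IndelSpec, SyntheticTruth, inject_indels

        truth = SyntheticTruth()
        cat = inject_indels(
            MutationCatalog("s"), small_sg, IndelSpec(200, 200, 0), seed=65, truth=truth
        )
        cls = classify_all(cat.indels, small_sg.genome)
        rep = [c.record.length for c in cls if c.klass == "repeat"]
        mh = [c.record.length for c in cls if c.klass == "microhomology"]
        res = ks_two_sample(rep, mh)
        assert res.p_value < 1e-10  # repeats are short, MH deletions longer


def _mock_deletions(lengths, mh_lengths):
    out = []
    for i, (L, m) in enumerate(zip(lengths, mh_lengths)):
        rec = IndelRecord("s", "c", 100 + 60 * i, "deletion", "A" * L, L)
        out.append(IndelClassification(rec, "x", mh_length=int(m)))
    return out


class TestExpectedMicrohomology:
    def test_uniform_composition_closed_form(self):
        comp = {b: 0.25 for b in "ACGT"}
        dels = _mock_deletions([10] * 100, [0] * 100)
        exp = expected_microhomology(dels, comp)
        assert exp.match_probability == pytest.approx(0.25)
        # P(mh >= 1) with two junction sides = 1 - (1 - 1/4)^2
        tail1 = exp.table.expected[1:].sum()
        assert tail1 / 100 == pytest.approx(1 - 0.75**2, abs=1e-9)
        assert exp.table.expected.sum() == pytest.approx(100.0)

    def test_expectation_matches_monte_carlo(self):
        """10^5 random junctions under uniform composition: simulated
        microhomology frequencies match the closed form within 2% relative
        error in the well-populated bins (Monte Carlo noise allows 10% for
        bins expecting fewer than 10,000 junctions)."""
        from mutforge.synthetic import _junction_mh

        rng = np.random.default_rng(66)
        L = 10
        n = 100_000
        counts = np.zeros(L + 1)
        bases = np.array(list("ACGT"))
        for _ in range(n):
            s = "".join(rng.choice(bases, size=L))
            left = "".join(rng.choice(bases, size=L))
            right = "".join(rng.choice(bases, size=L))
            counts[min(_junction_mh(s, left, right), L)] += 1
        comp = {b: 0.25 for b in "ACGT"}
        dels = _mock_deletions([L] * n, [0] * n)
        exp = expected_microhomology(dels, comp)
        for j in range(L + 1):
            e = exp.table.expected[j]
            if e < 100:
                continue
            assert counts[j] == pytest.approx(e, rel=0.02 if e >= 10_000 else 0.10)

    def test_null_calibration_chi_square_uniform(self):
        """Observed microhomology generated by the chance process itself:
        the chi-square p is uniform over 100 seeds (KS at alpha 0.01)."""
        from scipy.stats import kstest

        from mutforge.synthetic import _junction_mh

        comp = {b: 0.25 for b in "ACGT"}
        bases = np.array(list("ACGT"))
        pvals = []
        for s in range(100):
            rng = np.random.default_rng(12_000 + s)
            lengths = rng.integers(3, 15, size=500)
            mhs = []
            for L in lengths:
                sd = "".join(rng.choice(bases, size=int(L)))
                left = "".join(rng.choice(bases, size=50))
                right = "".join(rng.choice(bases, size=50))
                mhs.append(min(_junction_mh(sd, left, right), int(L)))
            dels = _mock_deletions(lengths, mhs)
            pvals.append(expected_microhomology(dels, comp).chi2_p)
        d, p = kstest(pvals, "uniform")
        assert p > 0.01

    def test_degenerate_composition_still_defined(self):
        dels = _mock_deletions([5] * 10, [5] * 10)
        exp = expected_microhomology(dels, {"A": 1.0, "C": 0.0, "G": 0.0, "T": 0.0})
        assert exp.match_probability == pytest.approx(1.0)
        assert np.isfinite(exp.table.expected).all()


class TestGroupComparison:
    def _cls(self, sample, klass, n):
        return [
            IndelClassification(
                IndelRecord(sample, "c", 10 + 3 * i, "deletion", "AAA", 3), klass
            )
            for i in range(n)
        ]

    def test_closed_form_odds_ratio(self):
        cls = (
            self._cls("a", "microhomology", 90) + self._cls("a", "none", 10)
            + self._cls("b", "microhomology", 10) + self._cls("b", "none", 90)
        )
        groups = {"a": "brca", "b": "sporadic"}
        res = group_comparison(cls, groups)
        assert res.odds_ratio == pytest.approx(81.0)
        assert res.p_value < 1e-10

    def test_identical_fractions_give_null(self):
        cls = (
            self._cls("a", "microhomology", 30) + self._cls("a", "none", 70)
            + self._cls("b", "microhomology", 30) + self._cls("b", "none", 70)
        )
        res = group_comparison(cls, {"a": "g1", "b": "g2"})
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_single_group_na(self):
        res = group_comparison(self._cls("a", "none", 5), {"a": "only"})
        assert np.isnan(res.p_value)

    def test_power_against_fivefold_mh_rate(self):
        """500 indels per group with a 5x MH-fraction differential: Fisher
        p < 1e-6 in at least 95/100 seeded replicates."""
        detected = 0
        for s in range(100):
            rng = np.random.default_rng(13_000 + s)
            n_a = int(rng.binomial(500, 0.5))  # MH fraction 0.5 in group a
            n_b = int(rng.binomial(500, 0.1))  # 5x lower in group b
            cls = (
                self._cls("a", "microhomology", n_a) + self._cls("a", "none", 500 - n_a)
                + self._cls("b", "microhomology", n_b) + self._cls("b", "none", 500 - n_b)
            )
            res = group_comparison(cls, {"a": "brca", "b": "sporadic"})
            if res.p_value < 1e-6:
                detected += 1
        assert detected >= 95
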