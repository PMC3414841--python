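"""Rainfall series, kataegis calling, processivity, and colocalization."""

import numpy as np
import pytest

from mutforge.catalog import MutationCatalog, RearrangementRecord, SubstitutionRecord
from mutforge.kataegis import (
    call_kataegis,
    cluster_spectrum,
    processive_segments,
    rainfall,
    rearrangement_colocalization,
    same_phase_fraction,
)


def _cat(positions, sample="s", chrom="chr1", ref="C", alt="T"):
    recs = [SubstitutionRecord(sample, chrom, p, ref, alt) for p in positions]
    return MutationCatalog(sample, recs)


class TestRainfall:
    def test_imds_within_chromosome(self):
        series = rainfall(_cat([10, 110, 1110]))
        assert [p.imd for p in series.points] == [None, 100, 1000]

    def test_one_mutation_per_chromosome_all_undefined(self):
        recs = [SubstitutionRecord("s", f"chr{i}", 100, "C", "T") for i in range(1, 5)]
        series = rainfall(MutationCatalog("s", recs))
        assert all(p.imd is None for p in series.points)

    def test_undefined_count_equals_chromosomes_with_mutations(self):
        rng = np.random.default_rng(0)
        recs = []
        seen = set()
        for _ in range(300):
            chrom = f"chr{rng.integers(1, 6)}"
            pos = int(rng.integers(1, 10_000))
            if (chrom, pos) in seen:
                continue
            seen.add((chrom, pos))
            recs.append(SubstitutionRecord("s", chrom, pos, "C", "T"))
        series = rainfall(MutationCatalog("s", recs))
        n_undef = sum(p.imd is None for p in series.points)
        assert n_undef == len({c for c, _ in seen})
        assert all(p.imd >= 1 for p in series.points if p.imd is not None)

    def test_input_order_irrelevant(self):
        a = rainfall(_cat([500, 100, 300]))
        b = rainfall(_cat([100, 300, 500]))
        assert [(p.pos, p.imd) for p in a.points] == [(p.pos, p.imd) for p in b.points]


class TestCallKataegis:
    def test_single_dense_cluster_called(self):
        # 20 mutations 100 bp apart within a sparse background
        positions = [10_000 + 100 * i for i in range(20)]
        background = [200_000 + 100_000 * i for i in range(10)]
        clusters, _ = call_kataegis(rainfall(_cat(positions + background)))
        assert len(clusters) == 1
        assert clusters[0].n == 20

    def test_below_min_size_not_called(self):
        positions = [10_000 + 100 * i for i in range(5)]
        clusters, _ = call_kataegis(rainfall(_cat(positions)))
        assert clusters == []

    def test_cluster_maximality(self):
        """No called cluster can be extended by an adjacent mutation without
        violating the IMD threshold."""
        rng = np.random.default_rng(1)
        positions = sorted(rng.choice(10_000_000, size=2000, replace=False) + 1)
        cluster = [5_000_000 + 80 * i for i in range(12)]
        positions = sorted(set(positions) | set(cluster))
        series = rainfall(_cat(positions))
        clusters, _ = call_kataegis(series, min_cluster_size=6, imd_threshold=1000)
        pos_list = [p.pos for p in series.points]
        for cl in clusters:
            i0, i1 = pos_list.index(cl.start), pos_list.index(cl.end)
            if i0 > 0:
                assert cl.start - pos_list[i0 - 1] > 1000
            if i1 < len(pos_list) - 1:
                assert pos_list[i1 + 1] - cl.end > 1000

    def test_false_positive_rate_under_uniform_null(self):
        """3,000 uniform mutations on a 3 Gb toy genome yield a spurious
        cluster in at most 5% of 100 seeds."""
        from mutforge.synthetic import simulate_uniform_catalog

        lengths = {f"chr{i}": 125_000_000 for i in range(1, 25)}
        fp = 0
        for s in range(100):
            cat = simulate_uniform_catalog(lengths, 3000, seed=7000 + s)
            clusters, _ = call_kataegis(rainfall(cat))
            fp += bool(clusters)
        assert fp <= 5

    def test_macrocluster_aggregation(self):
        c1 = [1_000_000 + 100 * i for i in range(8)]
        c2 = [1_500_000 + 100 * i for i in range(8)]  # 0.5 Mb gap: same macro
        c3 = [9_000_000 + 100 * i for i in range(8)]  # far: separate macro
        clusters, macros = call_kataegis(rainfall(_cat(c1 + c2 + c3)))
        assert len(clusters) == 3
        assert len(macros) == 2
        assert len(macros[0].clusters) == 2


class TestClusterSpectrum:
    def test_injected_tpc_cluster_composition(self, small_sg):
        from mutforge.synthetic import (
            KataegisSpec,
            SyntheticTruth,
            inject_kataegis,
        )

        truth = SyntheticTruth()
        spec = KataegisSpec(
            clusters_per_sample=1, cluster_size=30,
            class_probs={"C>T": 1.0}, strand_switch_prob=0.0,
        )
        cat = inject_kataegis(MutationCatalog("k"), small_sg, spec, seed=3, truth=truth)
        clusters, _ = call_kataegis(rainfall(cat))
        assert len(clusters) == 1
        cs = cluster_spectrum(clusters[0], small_sg.genome)
        assert cs.tpc_fraction == 1.0
        assert clusters[0].c_to_t_fraction == 1.0
        # -1 position is 100% T by construction
        assert cs.flank_composition.loc[-1, "T"] == pytest.approx(1.0)

    def test_class_fractions_sum_to_one(self, small_sg):
        from mutforge.synthetic import KataegisSpec, SyntheticTruth, inject_kataegis

        truth = SyntheticTruth()
        cat = inject_kataegis(
            MutationCatalog("k"), small_sg, KataegisSpec(clusters_per_sample=1),
            seed=5, truth=truth,
        )
        clusters, _ = call_kataegis(rainfall(cat))
        cs = cluster_spectrum(clusters[0], small_sg.genome)
        assert sum(cs.class_fractions.values()) == pytest.approx(1.0)

    def test_flank_composition_matches_brute_force_tally(self, small_sg):
        from mutforge.catalog import reverse_complement
        from mutforge.synthetic import KataegisSpec, SyntheticTruth, inject_kataegis

        truth = SyntheticTruth()
        spec = KataegisSpec(clusters_per_sample=1, cluster_size=30)
        cat = inject_kataegis(MutationCatalog("k"), small_sg, spec, seed=6, truth=truth)
        clusters, _ = call_kataegis(rainfall(cat))
        cl = clusters[0]
        cs = cluster_spectrum(cl, small_sg.genome)
        tallies = {off: {b: 0 for b in "ACGT"} for off in range(-10, 11)}
        n = 0
        seq = small_sg.genome.sequence(cl.chrom)
        for p in cl.members:
            if not p.mut_class.startswith("C"):
                continue
            w = seq[p.pos - 11 : p.pos + 10]
            if p.ref in "AG":
                w = reverse_complement(w)
            n += 1
            for off, base in zip(range(-10, 11), w):
                tallies[off][base] += 1
        for off in range(-10, 11):
            for b in "ACGT":
                assert cs.flank_composition.loc[off, b] == pytest.approx(tallies[off][b] / n)

    def test_phase_annotation_consumed(self, small_sg):
        from mutforge.synthetic import KataegisSpec, SyntheticTruth, inject_kataegis

        truth = SyntheticTruth()
        spec = KataegisSpec(clusters_per_sample=2)
        cat = inject_kataegis(MutationCatalog("k"), small_sg, spec, seed=8, truth=truth)
        clusters, _ = call_kataegis(rainfall(cat))
        for cl in clusters:
            assert same_phase_fraction(cl, truth.phases["k"]) == 1.0


class TestProcessivity:
    def test_run_partition(self):
        recs = (
            [SubstitutionRecord("s", "chr1", 100 + i, "C", "T") for i in range(0, 6, 2)]
            + [SubstitutionRecord("s", "chr1", 200 + i, "G", "A") for i in range(0, 4, 2)]
        )
        segs = processive_segments(MutationCatalog("s", recs))
        assert [(s.strand_class, s.run_length) for s in segs] == [("C>T", 3), ("G>A", 2)]

    def test_alternating_classes_give_unit_runs(self):
        recs = []
        for i in range(10):
            ref, alt = ("C", "T") if i % 2 == 0 else ("G", "A")
            recs.append(SubstitutionRecord("s", "chr1", 100 + 10 * i, ref, alt))
        segs = processive_segments(MutationCatalog("s", recs))
        assert all(s.run_length == 1 for s in segs)

    def test_mean_run_length_of_iid_two_class_sequence(self):
        """For an i.i.d. equiprobable two-class sequence the run length is
        geometric with mean 2; the empirical mean falls within 3 SE."""
        rng = np.random.default_rng(9)
        n = 10_000
        recs = []
        for i in range(n):
            ref, alt = ("C", "T") if rng.random() < 0.5 else ("G", "A")
            recs.append(SubstitutionRecord("s", "chr1", 1 + 2 * i, ref, alt))
        segs = processive_segments(MutationCatalog("s", recs))
        lengths = np.array([s.run_length for s in segs])
        # var of geometric(p=1/2) run length is 2; SE of the mean over ~n/2 runs
        se = np.sqrt(2 / len(lengths))
        assert abs(lengths.mean() - 2.0) <= 3 * se


class TestColocalization:
    def test_breakpoint_inside_cluster_distance_zero(self):
        positions = [10_000 + 100 * i for i in range(10)]
        series = rainfall(_cat(positions))
        clusters, macros = call_kataegis(series)
        mid = (clusters[0].start + clusters[0].end) // 2
        rearr = [RearrangementRecord("s", "chr1", mid, "chr2", 999)]
        res = rearrangement_colocalization(
            clusters, macros, rearr, {"chr1": 1_000_000, "chr2": 1_000_000}
        )
        assert res.nearest_breakpoint[0] == 0.0

    def test_rate_ratio_matches_arithmetic(self):
        """17 breakpoints in a 14 Mb region vs 7 in the remaining 157 Mb
        gives a per-Mb rate ratio of about 27.2."""
        positions = [20_000_000 + 500 * i for i in range(10)]
        series = rainfall(_cat(positions))
        clusters, macros = call_kataegis(series)
        macros[0].start, macros[0].end = 20_000_000, 34_000_000 - 1  # 14 Mb
        rng = np.random.default_rng(10)
        rearr = [
            RearrangementRecord("s", "chr1", int(p), "chr2", 1)
            for p in rng.integers(20_000_000, 34_000_000, size=17)
        ] + [
            RearrangementRecord("s", "chr1", int(p), "chr2", 1)
            for p in list(rng.integers(1, 20_000_000, size=4))
            + list(rng.integers(34_000_000, 171_000_000, size=3))
        ]
        res = rearrangement_colocalization(
            clusters, macros, rearr, {"chr1": 171_000_000, "chr2": 10}
        )
        rep = res.macro_reports[0]
        assert rep["breakpoints_inside"] == 17
        assert rep["breakpoints_outside"] == 7
        assert rep["rate_ratio"] == pytest.approx((17 / 14) / (7 / 157), rel=1e-3)

    def test_no_rearrangements_gives_undefined_distance(self):
        positions = [10_000 + 100 * i for i in range(10)]
        clusters, macros = call_kataegis(rainfall(_cat(positions)))
        res = rearrangement_colocalization(clusters, macros, [], {"chr1": 1_000_000})
        assert res.nearest_breakpoint[0] == float("inf")

    def test_enrichment_p_uniform_under_uniform_breakpoints(self):
        """With breakpoints scattered uniformly, the one-sided binomial
        enrichment p over 200 seeds is (super)uniform on [0, 1]."""
        from scipy.stats import kstest

        positions = [10_000 + 100 * i for i in range(10)]
        clusters, macros = call_kataegis(rainfall(_cat(positions)))
        macros[0].start, macros[0].end = 1, 300_000  # 30% of the chromosome
        pvals = []
        for s in range(200):
            rng = np.random.default_rng(8000 + s)
            rearr = [
                RearrangementRecord("s", "chr1", int(p), "chr2", 1)
                for p in rng.integers(1, 1_000_001, size=200)
            ]
            res = rearrangement_colocalization(
                clusters, macros, rearr, {"chr1": 1_000_000, "chr2": 10}
            )
            pvals.append(res.macro_reports[0]["binomial_p"])
        d, _ = kstest(pvals, "uniform")
        # one-sided exact binomial p on discrete counts is conservative;
        # allow the discreteness plus sampling noise
        assert d <= 0.13
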