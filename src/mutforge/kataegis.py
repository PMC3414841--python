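"""Regional hypermutation (kataegis) detection from intermutation distances.

A rainfall series orders a sample's substitutions genome-wide and attaches
to each the distance to the previous mutation on the same chromosome (IMD).
Kataegis microclusters are maximal runs of mutations whose successive IMDs
stay below a threshold; nearby microclusters aggregate into macroclusters.
The characteristic kataegis spectrum is C>T and C>G at TpC dinucleotides,
laid down processively on one chromosomal strand, near rearrangements.

The calling rule (>= 6 mutations, successive IMD <= 1 kb, macrocluster gap
<= 1 Mb) is an explicit operationalization; all three knobs are parameters
and are echoed into output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .catalog import MutationCatalog, RearrangementRecord, ReferenceGenome


@dataclass
class RainfallPoint:
    chrom: str
    pos: int
    imd: int | None  # None for the first mutation on each chromosome
    mut_class: str  # e.g. "C>T" (pyrimidine-collapsed)
    ref: str
    alt: str


@dataclass
class RainfallSeries:
    sample_id: str
    points: list[RainfallPoint]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": range(len(self.points)),
                "chrom": [p.chrom for p in self.points],
                "pos": [p.pos for p in self.points],
                "imd": [p.imd for p in self.points],
                "class": [p.mut_class for p in self.points],
            }
        )


def _pyrimidine_class(ref: str, alt: str) -> str:
    if ref in "AG":
        from .catalog import reverse_complement

        ref, alt = reverse_complement(ref), reverse_complement(alt)
    return f"{ref}>{alt}"


def rainfall(catalog: MutationCatalog) -> RainfallSeries:
    """Intermutation distances within chromosomes; the first mutation of
    each chromosome has an undefined IMD."""
    points: list[RainfallPoint] = []
    prev_chrom, prev_pos = None, None
    for r in catalog.substitutions:  # already (chrom, pos) sorted
        imd = r.pos - prev_pos if r.chrom == prev_chrom else None
        points.append(
            RainfallPoint(r.chrom, r.pos, imd, _pyrimidine_class(r.ref, r.alt), r.ref, r.alt)
        )
        prev_chrom, prev_pos = r.chrom, r.pos
    return RainfallSeries(catalog.sample_id, points)


@dataclass
class KataegisCluster:
    chrom: str
    start: int
    end: int
    members: list[RainfallPoint]
    tpc_fraction: float | None = None  # C>X members with 5' T; None until annotated
    c_to_t_fraction: float | None = None
    c_to_g_fraction: float | None = None

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def mean_imd(self) -> float:
        imds = [p.imd for p in self.members[1:]]
        return float(np.mean(imds)) if imds else 0.0


@dataclass
class Macrocluster:
    chrom: str
    start: int
    end: int
    clusters: list[KataegisCluster]


def call_kataegis(
    series: RainfallSeries,
    min_cluster_size: int = 6,
    imd_threshold: int = 1000,
    macro_gap: int = 1_000_000,
) -> tuple[list[KataegisCluster], list[Macrocluster]]:
    """Maximal same-chromosome runs with successive IMDs <= ``imd_threshold``
    and length >= ``min_cluster_size``; clusters separated by
    <= ``macro_gap`` aggregate into macroclusters."""
    clusters: list[KataegisCluster] = []
    run: list[RainfallPoint] = []

    def flush() -> None:
        if len(run) >= min_cluster_size:
            clusters.append(
                KataegisCluster(run[0].chrom, run[0].pos, run[-1].pos, list(run))
            )
        run.clear()

    for p in series.points:
        if run and p.chrom == run[-1].chrom and p.imd is not None and p.imd <= imd_threshold:
            run.append(p)
        else:
            flush()
            run.append(p)
    flush()

    macros: list[Macrocluster] = []
    for cl in clusters:
        if (
            macros
            and macros[-1].chrom == cl.chrom
            and cl.start - macros[-1].end <= macro_gap
        ):
            macros[-1].clusters.append(cl)
            macros[-1].end = cl.end
        else:
            macros.append(Macrocluster(cl.chrom, cl.start, cl.end, [cl]))
    return clusters, macros


@dataclass
class ClusterSpectrum:
    n_c_members: int
    flank_composition: pd.DataFrame | None  # rows = positions -10..10, cols = ACGT
    tpc_fraction: float | None
    class_fractions: dict[str, float]


def cluster_spectrum(
    cluster: KataegisCluster, genome: ReferenceGenome, flank: int = 10
) -> ClusterSpectrum:
    """Base composition of the +/- ``flank`` bp around C>X members
    (strand-collapsed so the mutated base reads as a pyrimidine), with the
    TpC fraction (5' T) and the cluster's class fractions."""
    from .catalog import reverse_complement

    classes = [p.mut_class for p in cluster.members]
    class_fractions = {
        c: classes.count(c) / len(classes) for c in sorted(set(classes))
    }
    windows: list[str] = []
    tpc = 0
    for p in cluster.members:
        if not p.mut_class.startswith("C"):
            continue
        seq = genome.slice(p.chrom, p.pos - flank, p.pos + flank)
        if len(seq) != 2 * flank + 1 or "N" in seq:
            continue
        if p.ref in "AG":  # pyrimidine on the reverse strand
            seq = reverse_complement(seq)
        windows.append(seq)
        if seq[flank - 1] == "T":
            tpc += 1
    cluster.c_to_t_fraction = class_fractions.get("C>T", 0.0)
    cluster.c_to_g_fraction = class_fractions.get("C>G", 0.0)
    if not windows:
        cluster.tpc_fraction = None
        return ClusterSpectrum(0, None, None, class_fractions)
    comp = pd.DataFrame(
        0, index=range(-flank, flank + 1), columns=list("ACGT"), dtype=float
    )
    for w in windows:
        for offset, base in zip(range(-flank, flank + 1), w):
            comp.loc[offset, base] += 1
    comp /= len(windows)
    cluster.tpc_fraction = tpc / len(windows)
    return ClusterSpectrum(len(windows), comp, cluster.tpc_fraction, class_fractions)


@dataclass
class ProcessiveSegment:
    chrom: str
    start: int
    end: int
    strand_class: str  # forward-strand ref>alt, e.g. "C>T" vs "G>A"
    members: list[RainfallPoint]

    @property
    def run_length(self) -> int:
        return len(self.members)


def processive_segments(
    catalog: MutationCatalog, region: tuple[str, int, int] | None = None
) -> list[ProcessiveSegment]:
    """Maximal runs of consecutive mutations sharing the identical
    forward-strand ref>alt change (C>T kept distinct from G>A)."""
    series = rainfall(catalog)
    pts = series.points
    if region is not None:
        chrom, start, end = region
        pts = [p for p in pts if p.chrom == chrom and start <= p.pos <= end]
    segments: list[ProcessiveSegment] = []
    run: list[RainfallPoint] = []

    def flush() -> None:
        if run:
            segments.append(
                ProcessiveSegment(
                    run[0].chrom, run[0].pos, run[-1].pos, f"{run[0].ref}>{run[0].alt}", list(run)
                )
            )
        run.clear()

    for p in pts:
        if run and p.chrom == run[-1].chrom and (p.ref, p.alt) == (run[-1].ref, run[-1].alt):
            run.append(p)
        else:
            flush()
            run.append(p)
    flush()
    return segments


def run_length_distribution(segments: Sequence[ProcessiveSegment]) -> pd.Series:
    lengths = pd.Series([s.run_length for s in segments])
    return lengths.value_counts().sort_index()


@dataclass
class ColocalizationResult:
    nearest_breakpoint: list[float]  # per cluster; inf when no rearrangements
    macro_reports: list[dict]  # per macrocluster: counts, rates, binomial p


def _breakpoint_positions(
    rearrangements: Sequence[RearrangementRecord],
) -> dict[str, np.ndarray]:
    pos: dict[str, list[int]] = {}
    for r in rearrangements:
        pos.setdefault(r.chrom_a, []).append(r.pos_a)
        pos.setdefault(r.chrom_b, []).append(r.pos_b)
    return {c: np.sort(np.asarray(p)) for c, p in pos.items()}


def rearrangement_colocalization(
    clusters: Sequence[KataegisCluster],
    macros: Sequence[Macrocluster],
    rearrangements: Sequence[RearrangementRecord],
    chrom_lengths: dict[str, int],
) -> ColocalizationResult:
    """Per-cluster nearest-breakpoint distance, and per-macrocluster
    breakpoint enrichment: counts inside the macro region vs the rest of
    its chromosome, per-Mb rates, and a one-sided binomial p with region
    length as exposure."""
    bp = _breakpoint_positions(rearrangements)
    nearest: list[float] = []
    for cl in clusters:
        arr = bp.get(cl.chrom)
        if arr is None or len(arr) == 0:
            nearest.append(float("inf"))
            continue
        inside = (arr >= cl.start) & (arr <= cl.end)
        if inside.any():
            nearest.append(0.0)
        else:
            d = np.minimum(np.abs(arr - cl.start), np.abs(arr - cl.end))
            nearest.append(float(d.min()))
    reports = []
    for mc in macros:
        arr = bp.get(mc.chrom, np.array([], dtype=int))
        chrom_len = chrom_lengths[mc.chrom]
        region_len = mc.end - mc.start + 1
        n_in = int(((arr >= mc.start) & (arr <= mc.end)).sum())
        n_total = len(arr)
        n_out = n_total - n_in
        p_region = region_len / chrom_len
        rate_in = n_in / (region_len / 1e6)
        out_len = max(chrom_len - region_len, 1)
        rate_out = n_out / (out_len / 1e6)
        pval = float(binom.sf(n_in - 1, n_total, p_region)) if n_total else float("nan")
        reports.append(
            {
                "chrom": mc.chrom,
                "start": mc.start,
                "end": mc.end,
                "breakpoints_inside": n_in,
                "breakpoints_outside": n_out,
                "rate_inside_per_mb": rate_in,
                "rate_outside_per_mb": rate_out,
                "rate_ratio": rate_in / rate_out if rate_out > 0 else float("inf"),
                "binomial_p": pval,
            }
        )
    return ColocalizationResult(nearest, reports)


def same_phase_fraction(
    cluster: KataegisCluster, phases: dict[tuple[str, int], str]
) -> float | None:
    """Fraction of cluster members sharing the modal phase label.

    Phase is consumed as an input annotation (e.g. from the generator or an
    upstream read-based phaser), never inferred here.  Members without an
    annotation are ignored; None when no member is annotated.
    """
    labels = [phases[(p.chrom, p.pos)] for p in cluster.members if (p.chrom, p.pos) in phases]
    if not labels:
        return None
    modal = max(set(labels), key=labels.count)
    return labels.count(modal) / len(labels)


def clusters_to_frame(clusters: Sequence[KataegisCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in clusters],
            "start": [c.start for c in clusters],
            "end": [c.end for c in clusters],
            "n": [c.n for c in clusters],
            "span": [c.span for c in clusters],
            "mean_imd": [c.mean_imd for c in clusters],
            "tpc_fraction": [c.tpc_fraction for c in clusters],
            "c_to_t_fraction": [c.c_to_t_fraction for c in clusters],
            "c_to_g_fraction": [c.c_to_g_fraction for c in clusters],
        }
    )


def clusters_to_bed(clusters: Sequence[KataegisCluster], path) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(clusters):
            fh.write(f"{c.chrom}\t{c.start - 1}\t{c.end}\tkataegis_{i}\t{c.n}\n")
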