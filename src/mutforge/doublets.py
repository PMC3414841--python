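"""Double-nucleotide substitutions and the Monte Carlo adjacency test.

Two substitutions at consecutive positions in the same sample form a
double substitution (doublet); runs of three or more consecutive
substituted positions are complex events and excluded from doublet counts.
The enrichment test asks whether the observed number of adjacent pairs
exceeds what uniform placement of the same per-chromosome, per-class
mutation counts would produce: each simulation re-places every mutation
uniformly at random (without positional collision) and records the
adjacent-pair count; the empirical p-value is
(1 + #{simulations >= observed}) / (n_sims + 1), so it is never exactly 0
and attains 1/(n_sims+1) when no simulation reaches the observed count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import MutationCatalog, SubstitutionRecord, reverse_complement
from .kataegis import _pyrimidine_class


@dataclass(frozen=True)
class DoubletRecord:
    sample_id: str
    chrom: str
    pos: int  # first base of the pair
    ref: str  # dinucleotide
    alt: str
    label: str  # canonical strand-collapsed, e.g. "CC>AA"


def canonical_doublet_label(ref: str, alt: str) -> str:
    """Strand-collapsed doublet label: a doublet and its reverse complement
    share one canonical label (the lexicographically smaller of the two)."""
    fwd = f"{ref}>{alt}"
    rev = f"{reverse_complement(ref)}>{reverse_complement(alt)}"
    return min(fwd, rev)


def find_adjacent_runs(
    catalog: MutationCatalog,
) -> tuple[list[DoubletRecord], list[list[SubstitutionRecord]]]:
    """Partition substitutions into maximal runs of consecutive positions.

    Runs of length 2 become doublets; length >= 3 become complex runs and
    are excluded from doublet counts.  Together with singletons this is a
    partition: every substitution belongs to exactly one category.
    """
    doublets: list[DoubletRecord] = []
    complex_runs: list[list[SubstitutionRecord]] = []
    run: list[SubstitutionRecord] = []

    def flush() -> None:
        if len(run) == 2:
            a, b = run
            doublets.append(
                DoubletRecord(
                    a.sample_id, a.chrom, a.pos, a.ref + b.ref, a.alt + b.alt,
                    canonical_doublet_label(a.ref + b.ref, a.alt + b.alt),
                )
            )
        elif len(run) >= 3:
            complex_runs.append(list(run))
        run.clear()

    for r in catalog.substitutions:
        if run and r.chrom == run[-1].chrom and r.pos == run[-1].pos + 1:
            run.append(r)
        else:
            flush()
            run.append(r)
    flush()
    return doublets, complex_runs


def enumerate_canonical_labels() -> list[str]:
    """All canonical doublet classes (both bases substituted): 78 labels."""
    labels = set()
    bases = "ACGT"
    for r1 in bases:
        for r2 in bases:
            for a1 in bases:
                for a2 in bases:
                    if a1 != r1 and a2 != r2:
                        labels.add(canonical_doublet_label(r1 + r2, a1 + a2))
    return sorted(labels)


def doublet_spectrum(doublets: Sequence[DoubletRecord]) -> pd.Series:
    """Counts over canonical doublet classes; sums to the doublet count."""
    counts = pd.Series(0, index=enumerate_canonical_labels(), dtype=int)
    for d in doublets:
        counts[d.label] += 1
    return counts


def ref_dinucleotide_summary(doublets: Sequence[DoubletRecord]) -> pd.Series:
    """Collapsed summary over the canonical reference dinucleotide alone."""
    counts: dict[str, int] = {}
    for d in doublets:
        ref = d.label.split(">")[0]
        counts[ref] = counts.get(ref, 0) + 1
    return pd.Series(counts).sort_index()


@dataclass
class MonteCarloResult:
    observed: int
    n_sims: int
    sim_mean: float
    sim_max: int
    fold_enrichment: float  # inf (with flag) when no simulated pair ever occurs
    empirical_p: float
    seed: int
    infinite_fold: bool = False


def sample_unique_positions(
    rng: np.random.Generator, length: int, n: int
) -> np.ndarray:
    """n distinct positions in 1..length, uniform without replacement.

    Drawn by over-sampling and de-duplicating, which is fast when n << length
    and still correct (falls back to a permutation for dense cases).
    """
    if n > length:
        raise ValueError(f"cannot place {n} mutations on a chromosome of length {length}")
    if n > length // 3:
        return rng.permutation(length)[:n] + 1
    out = np.unique(rng.integers(1, length + 1, size=int(n * 1.2) + 8))
    while len(out) < n:
        extra = rng.integers(1, length + 1, size=n)
        out = np.unique(np.concatenate([out, extra]))
    return rng.permutation(out)[:n]


def _adjacent_pairs(positions: np.ndarray) -> int:
    if len(positions) < 2:
        return 0
    pos = np.sort(positions)
    return int((np.diff(pos) == 1).sum())


def observed_adjacent_pairs(catalog: MutationCatalog) -> int:
    total = 0
    for pos in catalog.positions_by_chrom().values():
        total += _adjacent_pairs(pos)
    return total


def monte_carlo_adjacency_test(
    catalog: MutationCatalog,
    chrom_lengths: dict[str, int],
    n_sims: int = 1000,
    seed: int = 0,
) -> MonteCarloResult:
    """Adjacency-enrichment test preserving per-chromosome per-class counts.

    Placement is uniform along each chromosome irrespective of base content,
    mirroring a null of independently scattered single substitutions.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    # per-chromosome, per-class observed counts
    counts: dict[str, dict[str, int]] = {}
    for r in catalog.substitutions:
        cls = _pyrimidine_class(r.ref, r.alt)
        counts.setdefault(r.chrom, {}).setdefault(cls, 0)
        counts[r.chrom][cls] += 1
    for chrom, by_class in counts.items():
        if chrom not in chrom_lengths:
            raise ValueError(f"no length for chromosome {chrom}")
        if sum(by_class.values()) > chrom_lengths[chrom]:
            raise ValueError(f"more mutations than positions on {chrom}")
    observed = observed_adjacent_pairs(catalog)
    rng = np.random.default_rng(seed)
    sim_counts = np.empty(n_sims, dtype=np.int64)
    for s in range(n_sims):
        total = 0
        for chrom, by_class in counts.items():
            n_chrom = sum(by_class.values())
            pos = sample_unique_positions(rng, chrom_lengths[chrom], n_chrom)
            total += _adjacent_pairs(pos)
        sim_counts[s] = total
    mean = float(sim_counts.mean())
    p = (1 + int((sim_counts >= observed).sum())) / (n_sims + 1)
    infinite = mean == 0 and observed > 0
    fold = float("inf") if infinite else (observed / mean if mean > 0 else 0.0)
    return MonteCarloResult(
        observed, n_sims, mean, int(sim_counts.max()), fold, p, seed, infinite
    )
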