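"""Signature extraction by nonnegative matrix factorization.

The 96 x M spectrum matrix A is factorized as A ~ W H with W (96 x k) the
signatures and H (k x M) the exposures, by Lee-Seung multiplicative updates
minimizing the Frobenius reconstruction error  (1/2)||A - WH||_F^2.
The number of signatures k is selected by consensus clustering over random
restarts: each run assigns every sample to its maximal-exposure signature,
the co-assignment frequencies form a consensus matrix, and the cophenetic
correlation of that matrix measures stability.  k is chosen among the
stable ranks (cophenetic >= threshold) at the elbow of the mean
reconstruction-error curve, resolving ambiguity toward the smaller k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import average, cophenet, dendrogram, linkage
from scipy.spatial.distance import squareform

from .catalog import ReferenceGenome
from .spectrum import SCHEME, SpectrumMatrix

_EPS = 1e-12


@dataclass
class NMFRun:
    W: np.ndarray  # 96 x k
    H: np.ndarray  # k x M
    seed: int
    frobenius_error: float
    iterations: int
    error_trajectory: list[float] = field(default_factory=list, repr=False)


def nmf_decompose(
    A: SpectrumMatrix | np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> NMFRun:
    """One multiplicative-update NMF run from a seeded random start.

    W and H are initialized i.i.d. uniform(0, 1] scaled by mean(A).  Updates
    stop when the relative change of the Frobenius error falls below ``tol``
    or after ``max_iter`` iterations.  The error is non-increasing across
    iterations (up to machine precision).
    """
    X = A.counts.astype(float) if isinstance(A, SpectrumMatrix) else np.asarray(A, float)
    n, m = X.shape
    if not 1 <= k <= min(n, m):
        raise ValueError(f"k={k} out of range for a {n}x{m} matrix")
    rng = np.random.default_rng(seed)
    scale = max(X.mean(), _EPS)
    W = (1.0 - rng.random((n, k))) * scale  # uniform (0, 1], never exactly 0
    H = 1.0 - rng.random((k, m))
    prev = np.linalg.norm(X - W @ H)
    trajectory = [float(prev)]
    it = 0
    for it in range(1, max_iter + 1):
        H *= (W.T @ X) / (W.T @ W @ H + _EPS)
        W *= (X @ H.T) / (W @ H @ H.T + _EPS)
        err = np.linalg.norm(X - W @ H)
        trajectory.append(float(err))
        if prev > 0 and (prev - err) / prev < tol:
            prev = err
            break
        prev = err
    return NMFRun(W, H, seed, float(prev), it, trajectory)


@dataclass
class ConsensusMatrix:
    """M x M co-assignment frequencies over restarts."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        C = np.asarray(self.matrix, float)
        if not np.allclose(C, C.T):
            raise ValueError("consensus matrix must be symmetric")
        self.matrix = C

    def cophenetic_coefficient(self) -> float:
        """Correlation between consensus distances (1 - C) and the
        cophenetic distances of their average-linkage dendrogram.
        A consensus with all-identical assignments at every run gives a
        zero-variance distance vector and is reported as 1 (fully stable).
        """
        D = 1.0 - self.matrix
        np.fill_diagonal(D, 0.0)
        d = squareform(D, checks=False)
        if np.ptp(d) < 1e-12:
            return 1.0
        Z = average(d)
        coeff, _ = cophenet(Z, d)
        return float(coeff)


def _consensus_from_runs(runs: list[NMFRun]) -> ConsensusMatrix:
    m = runs[0].H.shape[1]
    C = np.zeros((m, m))
    for run in runs:
        assign = run.H.argmax(axis=0)
        C += assign[:, None] == assign[None, :]
    C /= len(runs)
    return ConsensusMatrix(C)


@dataclass
class ModelSelectionResult:
    k_range: list[int]
    cophenetic: dict[int, float]
    mean_error: dict[int, float]
    n_runs: int
    chosen_k: int
    consensus: dict[int, ConsensusMatrix] = field(repr=False, default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "k": self.k_range,
                "cophenetic": [self.cophenetic[k] for k in self.k_range],
                "mean_error": [self.mean_error[k] for k in self.k_range],
            }
        )


def _choose_k(
    k_range: list[int],
    cophenetic: dict[int, float],
    mean_error: dict[int, float],
    threshold: float,
) -> int:
    """Stable ranks are the leading contiguous run with cophenetic >= the
    threshold; within it, pick the reconstruction-error elbow (the k with
    the greatest reduction in slope), ties toward the smaller k."""
    # the stable run ends at the first sharp drop: cophenetic below the
    # threshold and staying below at the next rank (an isolated dip is
    # consensus noise, not loss of stability)
    stable = []
    for i, k in enumerate(k_range):
        if cophenetic[k] >= threshold:
            stable.append(k)
        else:
            nxt = k_range[i + 1] if i + 1 < len(k_range) else None
            if nxt is None or cophenetic[nxt] < threshold:
                break
    if not stable:  # nothing stable: fall back to the most stable rank
        return max(k_range, key=lambda k: cophenetic[k])
    if len(stable) == 1:
        return stable[0]
    # elbow: the largest stable k with a marked reduction in slope - the
    # incoming error drop s(k) = e(k-1) - e(k) exceeding the outgoing drop
    # s(k+1) by at least elbow_ratio.  Ranks beyond the true one absorb
    # noise at a roughly constant slope (ratio near 1); when no marked
    # elbow exists the ambiguity is resolved toward the smallest stable k.
    elbow_ratio = 2.0
    min_drop_fraction = 0.05  # of the error range across the scanned ranks
    floor = 1e-9 * max(abs(mean_error[k]) for k in k_range)
    err_range = mean_error[k_range[0]] - mean_error[k_range[-1]]
    marked = []
    for k in stable:
        if k - 1 in mean_error and k + 1 in mean_error:
            s_in = mean_error[k - 1] - mean_error[k]
            s_out = mean_error[k] - mean_error[k + 1]
            if (
                s_in / max(s_out, floor) >= elbow_ratio
                and s_in >= min_drop_fraction * err_range
            ):
                marked.append(k)
    return max(marked) if marked else stable[0]


def select_rank(
    A: SpectrumMatrix | np.ndarray,
    k_range: range | list[int],
    n_runs: int = 100,
    seed: int = 0,
    cophenetic_threshold: float = 0.95,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> ModelSelectionResult:
    """Consensus model selection over ``k_range`` with ``n_runs`` seeded
    restarts per rank."""
    ks = sorted(k_range)
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    rng = np.random.default_rng(seed)
    coph: dict[int, float] = {}
    merr: dict[int, float] = {}
    consensus: dict[int, ConsensusMatrix] = {}
    for k in ks:
        seeds = rng.integers(0, 2**31 - 1, size=n_runs)
        runs = [nmf_decompose(A, k, seed=int(s), max_iter=max_iter, tol=tol) for s in seeds]
        consensus[k] = _consensus_from_runs(runs)
        coph[k] = consensus[k].cophenetic_coefficient()
        merr[k] = float(np.mean([r.frobenius_error for r in runs]))
    chosen = _choose_k(ks, coph, merr, cophenetic_threshold)
    return ModelSelectionResult(ks, coph, merr, n_runs, chosen, consensus)


@dataclass
class SignatureSet:
    """Normalized signatures with exposures in mutation counts and proportions."""

    signatures: np.ndarray  # 96 x k, columns sum to 1
    exposures: np.ndarray  # k x M, column j sums to sample j's fitted count
    samples: list[str]
    labels: list[str]
    source_run: NMFRun | None = None

    @property
    def k(self) -> int:
        return self.signatures.shape[1]

    @property
    def proportions(self) -> np.ndarray:
        tot = self.exposures.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.exposures / tot, 0.0)

    def write(self, sig_path, exp_path) -> None:
        import pandas as pd

        pd.DataFrame(self.signatures, index=SCHEME.labels, columns=self.labels).to_csv(
            sig_path, sep="\t", index_label="channel"
        )
        pd.DataFrame(self.exposures, index=self.labels, columns=self.samples).to_csv(
            exp_path, sep="\t", index_label="signature"
        )


def extract_signatures(
    A: SpectrumMatrix,
    k: int,
    n_runs: int = 100,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> SignatureSet:
    """Best-error run of ``n_runs`` restarts, with W columns normalized to
    sum 1 and H rescaled inversely so W_norm @ H_rescaled == W @ H."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    best = min(
        (nmf_decompose(A, k, seed=int(s), max_iter=max_iter, tol=tol) for s in seeds),
        key=lambda r: r.frobenius_error,
    )
    colsum = best.W.sum(axis=0)
    empty = colsum < 1e-9
    safe = np.where(empty, 1.0, colsum)
    W_norm = best.W / safe
    H_scaled = best.H * safe[:, None]
    labels = [f"S{i + 1}" for i in range(k)]
    if empty.any():
        for i in np.nonzero(empty)[0]:
            labels[i] += "(empty)"
    return SignatureSet(W_norm, H_scaled, list(A.samples), labels, best)


def trinucleotide_corrected_signatures(
    sigset: SignatureSet, genome: ReferenceGenome
) -> np.ndarray:
    """Display correction: divide each channel by the genome frequency of
    its context and renormalize columns to sum 1."""
    occ = np.array(
        [genome.trinucleotide_counts[SCHEME.context(i)] for i in range(96)], float
    )
    if (occ == 0).any():
        raise ValueError("a channel context has zero genome frequency")
    freq = occ / occ.sum()
    corrected = sigset.signatures / freq[:, None]
    return corrected / corrected.sum(axis=0, keepdims=True)


@dataclass
class Dendrogram:
    linkage_matrix: np.ndarray
    leaf_order: list[int]
    samples: list[str]


def cluster_samples(sigset: SignatureSet) -> Dendrogram:
    """Average-linkage hierarchical clustering of samples on Euclidean
    distances between signature-proportion vectors.  Leaf order is the
    deterministic scipy ordering (ties broken by original sample index)."""
    P = sigset.proportions.T  # M x k
    if P.shape[0] < 2:
        raise ValueError("need at least two samples to cluster")
    Z = linkage(P, method="average", metric="euclidean")
    order = dendrogram(Z, no_plot=True)["leaves"]
    return Dendrogram(Z, list(order), list(sigset.samples))
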