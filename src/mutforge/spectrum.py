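"""96-channel trinucleotide classification of base substitutions.

Every substitution is collapsed to a pyrimidine reference: a mutation of a
purine is reverse-complemented (together with its trinucleotide context)
before lookup, so there are 6 substitution classes (C>A, C>G, C>T, T>A, T>C,
T>G) x 16 flanking contexts = 96 channels.  Channel order is substitution
class first, then contexts lexicographic in (5' base, 3' base).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .catalog import (
    CpGIslandSet,
    MutationCatalog,
    ReferenceGenome,
    SubstitutionRecord,
    reverse_complement,
)

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"
SUBSTITUTION_CLASSES = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]


class ChannelScheme:
    """The fixed ordered list of 96 channel labels ``X[R>A]Z``."""

    def __init__(self) -> None:
        self.labels: list[str] = []
        for cls in SUBSTITUTION_CLASSES:
            ref, alt = cls[0], cls[2]
            for five in NUCLEOTIDES:
                for three in NUCLEOTIDES:
                    self.labels.append(f"{five}[{ref}>{alt}]{three}")
        self._index = {lab: i for i, lab in enumerate(self.labels)}
        assert len(self.labels) == 96

    def __len__(self) -> int:
        return 96

    def index(self, label: str) -> int:
        return self._index[label]

    def label(self, index: int) -> str:
        return self.labels[index]

    def context(self, index: int) -> str:
        """Pyrimidine-central trinucleotide context of a channel."""
        lab = self.labels[index]
        return lab[0] + lab[2] + lab[6]

    def substitution_class(self, index: int) -> str:
        return SUBSTITUTION_CLASSES[index // 16]


SCHEME = ChannelScheme()


class UnclassifiableError(ValueError):
    pass


def collapse_to_pyrimidine(ref: str, alt: str, context: str) -> tuple[str, str, str]:
    """Return (ref, alt, context) with a pyrimidine reference, reverse
    complementing all three when ref is a purine."""
    if context[1] != ref:
        raise ValueError(f"context {context!r} does not centre on ref {ref!r}")
    if ref in "AG":
        return (
            reverse_complement(ref),
            reverse_complement(alt),
            reverse_complement(context),
        )
    return ref, alt, context


def classify_substitution(record: SubstitutionRecord, context: str) -> int:
    """Channel index of a substitution given its forward-strand context.

    Raises :class:`UnclassifiableError` when the context contains N.
    """
    if "N" in context:
        raise UnclassifiableError(f"context {context!r} contains N")
    ref, alt, ctx = collapse_to_pyrimidine(record.ref, record.alt, context)
    return SCHEME.index(f"{ctx[0]}[{ref}>{alt}]{ctx[2]}")


@dataclass
class SpectrumMatrix:
    """96 x M matrix of channel counts, one column per sample."""

    counts: np.ndarray  # int, shape (96, M)
    samples: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (96, len(self.samples)):
            raise ValueError("spectrum matrix must be 96 x n_samples")
        if (self.counts < 0).any():
            raise ValueError("spectrum counts must be nonnegative")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.samples.index(sample_id)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=SCHEME.labels, columns=self.samples)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="channel")

    @classmethod
    def read(cls, path) -> "SpectrumMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != SCHEME.labels:
            raise ValueError("spectrum file channels do not match the 96-channel scheme")
        return cls(df.to_numpy(), [str(c) for c in df.columns])


def build_spectrum_matrix(
    catalogs: Sequence[MutationCatalog],
    genome: ReferenceGenome,
    exclude_positions: dict[str, set[tuple[str, int]]] | None = None,
) -> SpectrumMatrix:
    """Classify every substitution of every catalog into the 96 channels.

    Substitutions whose context is undefined (N or chromosome edge) are
    excluded with a logged count.  ``exclude_positions`` maps sample_id to
    (chrom, pos) pairs to leave out (e.g. members of multi-base runs).
    """
    if not catalogs:
        raise ValueError("need at least one catalog")
    counts = np.zeros((96, len(catalogs)), dtype=np.int64)
    for j, cat in enumerate(catalogs):
        skip = (exclude_positions or {}).get(cat.sample_id, set())
        dropped = 0
        if not cat.substitutions:
            logger.warning("catalog %s has no substitutions; zero column", cat.sample_id)
        for r in cat.substitutions:
            if (r.chrom, r.pos) in skip:
                continue
            try:
                ctx = genome.trinucleotide_context(r.chrom, r.pos)
                counts[classify_substitution(r, ctx), j] += 1
            except (ValueError, UnclassifiableError):
                dropped += 1
        if dropped:
            logger.info("sample %s: %d unclassifiable substitutions excluded",
                        cat.sample_id, dropped)
    return SpectrumMatrix(counts, [c.sample_id for c in catalogs])


@dataclass
class HeatmapMatrix:
    """Per-sample log rate of each channel per genome occurrence of its
    context; zero-count cells are masked rather than -inf."""

    values: np.ndarray  # float, shape (96, M); masked cells are nan
    mask: np.ndarray  # bool, shape (96, M); True where count was zero
    samples: list[str]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.values, index=SCHEME.labels, columns=self.samples)
        return df.mask(self.mask)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="channel", na_rep="NA")


def heatmap_values(spectrum: SpectrumMatrix, genome: ReferenceGenome) -> HeatmapMatrix:
    """log(count / genome occurrences of the channel's context), per cell."""
    occ = np.array(
        [genome.trinucleotide_counts[SCHEME.context(i)] for i in range(96)], dtype=float
    )
    if (occ == 0).any():
        missing = [SCHEME.context(i) for i in np.nonzero(occ == 0)[0]]
        raise ValueError(f"contexts absent from genome: {sorted(set(missing))}")
    counts = spectrum.counts.astype(float)
    mask = counts == 0
    with np.errstate(divide="ignore"):
        vals = np.log(counts / occ[:, None])
    vals[mask] = np.nan
    return HeatmapMatrix(vals, mask, list(spectrum.samples))


# ------------------------------------------------- CpG-island odds ratio

@dataclass
class OddsRatioResult:
    odds_ratio: float
    ci_low: float | None
    ci_high: float | None
    table: tuple[int, int, int, int]  # mut_out, risk_out, mut_in, risk_in
    zero_cell: bool = False


def cpg_site_positions(
    genome: ReferenceGenome, islands: CpGIslandSet
) -> tuple[list[tuple[str, int, str]], list[tuple[str, int, str]]]:
    """At-risk sites: cytosines within CpG dinucleotides on either strand
    (both the C and the G of every CG occurrence, the G carrying the
    reverse-strand C), as (chrom, 1-based pos, forward ref base), split
    (outside, inside) islands."""
    outside: list[tuple[str, int, str]] = []
    inside: list[tuple[str, int, str]] = []
    for chrom in genome.chromosomes:
        seq = genome.sequence(chrom)
        start = 0
        while True:
            i = seq.find("CG", start)
            if i == -1:
                break
            for pos, base in ((i + 1, "C"), (i + 2, "G")):
                (inside if islands.contains(chrom, pos) else outside).append(
                    (chrom, pos, base)
                )
            start = i + 1
    return outside, inside


def _cpg_cytosine_counts(genome: ReferenceGenome, islands: CpGIslandSet) -> tuple[int, int]:
    outside, inside = cpg_site_positions(genome, islands)
    return len(outside), len(inside)


def odds_ratio_from_table(
    mut_out: int, risk_out: int, mut_in: int, risk_in: int
) -> OddsRatioResult:
    """OR = (mut_out/(risk_out-mut_out)) / (mut_in/(risk_in-mut_in)) with a
    Woolf 95% log CI; any zero cell leaves the CI undefined (no silent
    continuity correction)."""
    a, b = mut_out, risk_out - mut_out
    c, d = mut_in, risk_in - mut_in
    if min(a, b, c, d) <= 0:
        odds = (a / b) / (c / d) if b > 0 and c > 0 and d > 0 else math.inf
        return OddsRatioResult(odds, None, None, (mut_out, risk_out, mut_in, risk_in), True)
    odds = (a / b) / (c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatioResult(
        odds,
        math.exp(math.log(odds) - 1.96 * se),
        math.exp(math.log(odds) + 1.96 * se),
        (mut_out, risk_out, mut_in, risk_in),
    )


def cpg_island_odds_ratio(
    catalogs: Sequence[MutationCatalog],
    genome: ReferenceGenome,
    islands: CpGIslandSet,
) -> OddsRatioResult:
    """Odds ratio of the XpCpG C>T mutation rate outside vs inside CpG islands.

    Events are C>T substitutions at a CpG dinucleotide (strand-collapsed, so
    G>A with a 5' C on the forward strand also counts).  At-risk sites are
    genome cytosines in CpG dinucleotides on either strand.  A value > 1
    means a higher rate outside islands, as expected if in-island CpGs are
    mostly unmethylated.  The 95% CI is the Woolf log interval.
    """
    mut_out = mut_in = 0
    for cat in catalogs:
        for r in cat.substitutions:
            try:
                ctx = genome.trinucleotide_context(r.chrom, r.pos)
                ref, alt, ctx_c = collapse_to_pyrimidine(r.ref, r.alt, ctx)
            except ValueError:
                continue
            if ref == "C" and alt == "T" and ctx_c[2] == "G":
                if islands.contains(r.chrom, r.pos):
                    mut_in += 1
                else:
                    mut_out += 1
    risk_out, risk_in = _cpg_cytosine_counts(genome, islands)
    return odds_ratio_from_table(mut_out, risk_out, mut_in, risk_in)
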