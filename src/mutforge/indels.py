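"""Indel architecture: tandem-repeat vs junction-microhomology classification.

A deletion or insertion is repeat-mediated when its sequence is a whole
number of copies of a short unit and at least one further whole unit lies
immediately adjacent in the reference (replication slippage).  A deletion
that is not repeat-mediated is microhomology-mediated when the junction
shows overlapping identity: the longest prefix of the deleted sequence
matching the sequence immediately 3' of the deletion, or the longest suffix
matching the sequence immediately 5', whichever is greater, reaches
``mh_min`` (default 2 bp — single-base matches arise at ~44% of junctions
by chance).  Repeat takes precedence: a deletion inside a tandem repeat
trivially shows junction identity.  Insertions are eligible for the repeat
class only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chisquare, fisher_exact, ks_2samp

from .catalog import IndelRecord, ReferenceGenome


@dataclass
class IndelClassification:
    record: IndelRecord
    klass: str  # repeat | microhomology | none
    repeat_unit: str = ""
    adjacent_repeat_copies: int = 0
    mh_length: int = 0
    truncated_flank: bool = False


def _smallest_unit(seq: str, max_unit: int) -> tuple[str, int] | None:
    """Smallest unit (length <= max_unit) whose whole copies tile ``seq``."""
    for u in range(1, min(max_unit, len(seq)) + 1):
        if len(seq) % u == 0 and seq == seq[:u] * (len(seq) // u):
            return seq[:u], len(seq) // u
    return None


def _match_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def classify_indel(
    record: IndelRecord,
    genome: ReferenceGenome,
    mh_min: int = 2,
    max_unit: int = 6,
    flank: int = 50,
) -> IndelClassification:
    """Classify one indel from its sequence and ±``flank`` bp of reference.

    For a deletion, the event occupies reference positions
    pos+1 .. pos+length; the 5' flank ends at ``pos`` and the 3' flank
    starts at pos+length+1.  For an insertion both flanks meet at the
    insertion point (between pos and pos+1).
    """
    if record.kind == "complex":
        return IndelClassification(record, "none")
    seq = record.seq
    chrom_len = len(genome.sequence(record.chrom))
    if record.kind == "deletion":
        left_end, right_start = record.pos, record.pos + record.length + 1
    else:
        left_end, right_start = record.pos, record.pos + 1
    left = genome.slice(record.chrom, left_end - flank + 1, left_end)
    right = genome.slice(record.chrom, right_start, right_start + flank - 1)
    truncated = (left_end - flank + 1 < 1) or (right_start + flank - 1 > chrom_len)

    # repeat check first
    unit_info = _smallest_unit(seq, max_unit)
    if unit_info is not None:
        unit, _ = unit_info
        copies = 0
        i = len(left)
        while i >= len(unit) and left[i - len(unit) : i] == unit:
            copies += 1
            i -= len(unit)
        j = 0
        while j + len(unit) <= len(right) and right[j : j + len(unit)] == unit:
            copies += 1
            j += len(unit)
        if copies >= 1:
            return IndelClassification(record, "repeat", unit, copies, 0, truncated)

    if record.kind == "insertion":
        return IndelClassification(record, "none", truncated_flank=truncated)

    mh = max(_match_len(seq, right), _match_len(seq[::-1], left[::-1]))
    klass = "microhomology" if mh >= mh_min else "none"
    return IndelClassification(record, klass, mh_length=mh, truncated_flank=truncated)


def classify_all(
    records: Sequence[IndelRecord],
    genome: ReferenceGenome,
    mh_min: int = 2,
    max_unit: int = 6,
) -> list[IndelClassification]:
    return [classify_indel(r, genome, mh_min, max_unit) for r in records]


@dataclass
class KSResult:
    statistic: float
    p_value: float
    n1: int
    n2: int


def ks_two_sample(lengths_repeat: Sequence[int], lengths_mh: Sequence[int]) -> KSResult:
    """Two-sample Kolmogorov-Smirnov comparison of indel length
    distributions (exact p for small samples, asymptotic otherwise)."""
    if not len(lengths_repeat) or not len(lengths_mh):
        return KSResult(float("nan"), float("nan"), len(lengths_repeat), len(lengths_mh))
    res = ks_2samp(lengths_repeat, lengths_mh, method="auto")
    return KSResult(float(res.statistic), float(res.pvalue), len(lengths_repeat), len(lengths_mh))


@dataclass
class MicrohomologyExpectation:
    table: pd.DataFrame  # per mh length: observed, expected
    chi2: float
    chi2_p: float
    match_probability: float


def _mh_survival(j: int, length: int, p: float) -> float:
    """P(junction microhomology >= j) for a deletion of given length under
    the chance model: per-position match probability p = sum_b p_b^2 on each
    side independently, runs capped at the deletion length, combined as the
    max of the two sides.  Exact under uniform base composition."""
    if j <= 0:
        return 1.0
    if j > length:
        return 0.0
    q = p**j
    return 1.0 - (1.0 - q) ** 2


def expected_microhomology(
    deletions: Sequence[IndelClassification],
    composition: dict[str, float],
    max_mh: int | None = None,
) -> MicrohomologyExpectation:
    """Observed vs chance-expected junction microhomology lengths.

    ``composition`` gives flank base frequencies (p_A..p_T); the chance of a
    per-position match is p = sum_b p_b^2 (0.25 for uniform composition).
    Expected counts are computed per deletion (the cap at the deletion
    length matters for short events) and summed; they total the number of
    deletions analyzed.  A chi-square summary pools bins to expected >= 5.
    """
    dels = [c for c in deletions if c.record.kind == "deletion"]
    if not dels:
        raise ValueError("no deletions to analyze")
    total = sum(composition.values())
    p = sum((v / total) ** 2 for v in composition.values())
    jmax = max_mh if max_mh is not None else max(c.record.length for c in dels)
    expected = np.zeros(jmax + 1)
    for c in dels:
        L = c.record.length
        for j in range(0, min(L, jmax) + 1):
            expected[j] += _mh_survival(j, L, p) - _mh_survival(j + 1, L, p)
    observed = np.zeros(jmax + 1)
    for c in dels:
        observed[min(c.mh_length, jmax)] += 1
    table = pd.DataFrame(
        {"mh_length": range(jmax + 1), "observed": observed, "expected": expected}
    )
    # pool the tail so every chi-square bin has expected >= 5
    obs_b, exp_b = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(observed, expected):
        acc_o += o
        acc_e += e
        if acc_e >= 5:
            obs_b.append(acc_o)
            exp_b.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 and exp_b:
        obs_b[-1] += acc_o
        exp_b[-1] += acc_e
    if len(exp_b) >= 2:
        chi2, pval = chisquare(obs_b, exp_b)
    else:
        chi2, pval = float("nan"), float("nan")
    return MicrohomologyExpectation(table, float(chi2), float(pval), p)


@dataclass
class GroupComparison:
    table: pd.DataFrame  # per group: mh count, other count, mh fraction
    odds_ratio: float
    p_value: float


def group_comparison(
    classifications: Sequence[IndelClassification],
    groups: dict[str, str],
) -> GroupComparison:
    """2x2 association of microhomology-mediated status with sample group
    (e.g. BRCA-null vs sporadic): Fisher exact test and odds ratio."""
    labels = sorted(set(groups.values()))
    if len(labels) < 2:
        return GroupComparison(pd.DataFrame(), float("nan"), float("nan"))
    if len(labels) > 2:
        raise ValueError("group_comparison requires exactly two groups")
    counts = {g: [0, 0] for g in labels}  # [mh, other]
    for c in classifications:
        g = groups.get(c.record.sample_id)
        if g is None:
            continue
        counts[g][0 if c.klass == "microhomology" else 1] += 1
    (a, b), (c_, d) = counts[labels[0]], counts[labels[1]]
    odds, p = fisher_exact([[a, b], [c_, d]])
    table = pd.DataFrame(
        {
            "group": labels,
            "microhomology": [a, c_],
            "other": [b, d],
            "mh_fraction": [
                a / (a + b) if a + b else math.nan,
                c_ / (c_ + d) if c_ + d else math.nan,
            ],
        }
    )
    return GroupComparison(table, float(odds), float(p))


def classification_frame(classifications: Sequence[IndelClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [c.record.sample_id for c in classifications],
            "chrom": [c.record.chrom for c in classifications],
            "pos": [c.record.pos for c in classifications],
            "kind": [c.record.kind for c in classifications],
            "length": [c.record.length for c in classifications],
            "class": [c.klass for c in classifications],
            "repeat_unit": [c.repeat_unit for c in classifications],
            "adjacent_repeat_copies": [c.adjacent_repeat_copies for c in classifications],
            "mh_length": [c.mh_length for c in classifications],
        }
    )
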