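"""Transcription-coupled analyses of somatic substitutions.

Strand assignment follows the pyrimidine-collapsed convention: with the
mutated pyrimidine on the forward strand, a gene transcribed from the +
strand has its template (transcribed) strand on the reverse, so the
pyrimidine sits on the untranscribed (coding) strand; the assignment flips
for - strand genes and for pyrimidines on the reverse strand.  Positions
covered by genes on both strands are ambiguous and excluded from tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .catalog import GeneAnnotation, MutationCatalog, ReferenceGenome, SubstitutionRecord
from .kataegis import _pyrimidine_class

CLASS_PAIRS = {
    "C>A": "C>A/G>T",
    "C>G": "C>G/G>C",
    "C>T": "C>T/G>A",
    "T>A": "T>A/A>T",
    "T>C": "T>C/A>G",
    "T>G": "T>G/A>C",
}


@dataclass
class StrandAssignedMutation:
    record: SubstitutionRecord
    assignment: str  # transcribed | untranscribed | intergenic | ambiguous
    gene_id: str | None
    mut_class: str  # pyrimidine-collapsed


def assign_strand(
    record: SubstitutionRecord, annotation: GeneAnnotation
) -> StrandAssignedMutation:
    genes = annotation.overlapping(record.chrom, record.pos)
    cls = _pyrimidine_class(record.ref, record.alt)
    if not genes:
        return StrandAssignedMutation(record, "intergenic", None, cls)
    strands = {g.strand for g in genes}
    if len(strands) > 1:
        return StrandAssignedMutation(record, "ambiguous", None, cls)
    gene = max(genes, key=lambda g: g.length)  # nested genes: longest transcript
    pyrimidine_on_forward = record.ref in "CT"
    if gene.strand == "+":
        assignment = "untranscribed" if pyrimidine_on_forward else "transcribed"
    else:
        assignment = "transcribed" if pyrimidine_on_forward else "untranscribed"
    return StrandAssignedMutation(record, assignment, gene.gene_id, cls)


def assign_all(
    catalog: MutationCatalog, annotation: GeneAnnotation
) -> list[StrandAssignedMutation]:
    return [assign_strand(r, annotation) for r in catalog.substitutions]


@dataclass
class StrandBiasResult:
    class_pair: str
    transcribed: int
    untranscribed: int
    expected_transcribed_proportion: float
    p_value: float | None  # None when no mutations in the class


def expected_strand_proportions(
    genome: ReferenceGenome, annotation: GeneAnnotation
) -> dict[str, float]:
    """At-risk correction: expected proportion of pyrimidine-class events on
    the transcribed strand, from the base composition of gene footprints.

    For a + strand gene, pyrimidines on the forward strand lie on the
    untranscribed strand; their complements (purines on the forward strand)
    put the pyrimidine on the transcribed strand.  Returns one proportion
    for C-reference classes and one for T-reference classes, keyed "C"/"T".
    """
    tr = {"C": 0, "T": 0}
    untr = {"C": 0, "T": 0}
    for gene in annotation:
        seq = genome.slice(gene.chrom, gene.tx_start, gene.tx_end)
        counts = {b: seq.count(b) for b in "ACGT"}
        if gene.strand == "+":
            untr["C"] += counts["C"]
            untr["T"] += counts["T"]
            tr["C"] += counts["G"]
            tr["T"] += counts["A"]
        else:
            tr["C"] += counts["C"]
            tr["T"] += counts["T"]
            untr["C"] += counts["G"]
            untr["T"] += counts["A"]
    out = {}
    for base in "CT":
        total = tr[base] + untr[base]
        out[base] = tr[base] / total if total else 0.5
    return out


def strand_bias_test(
    assigned: Sequence[StrandAssignedMutation],
    mut_class: str,
    expected_proportion: float | None = None,
    genome: ReferenceGenome | None = None,
    annotation: GeneAnnotation | None = None,
) -> StrandBiasResult:
    """Two-sided exact binomial test of the transcribed count for one
    pyrimidine class (e.g. "C>A" covers C>A/G>T)."""
    if expected_proportion is None:
        if genome is None or annotation is None:
            raise ValueError("need expected_proportion or genome + annotation")
        expected_proportion = expected_strand_proportions(genome, annotation)[mut_class[0]]
    n_tr = sum(
        1 for a in assigned if a.mut_class == mut_class and a.assignment == "transcribed"
    )
    n_untr = sum(
        1 for a in assigned if a.mut_class == mut_class and a.assignment == "untranscribed"
    )
    total = n_tr + n_untr
    pair = CLASS_PAIRS[mut_class]
    if total == 0:
        return StrandBiasResult(pair, 0, 0, expected_proportion, None)
    p = binomtest(n_tr, total, expected_proportion, alternative="two-sided").pvalue
    return StrandBiasResult(pair, n_tr, n_untr, expected_proportion, float(p))


def strand_bias_report(
    assigned: Sequence[StrandAssignedMutation],
    genome: ReferenceGenome,
    annotation: GeneAnnotation,
) -> pd.DataFrame:
    props = expected_strand_proportions(genome, annotation)
    rows = []
    for cls in CLASS_PAIRS:
        r = strand_bias_test(assigned, cls, expected_proportion=props[cls[0]])
        rows.append(
            {
                "class_pair": r.class_pair,
                "transcribed": r.transcribed,
                "untranscribed": r.untranscribed,
                "expected_transcribed_proportion": r.expected_transcribed_proportion,
                "p_value": r.p_value,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ExpressionBinProfile:
    table: pd.DataFrame  # per bin: mean_log2_expression, mutations_per_mb, gene_count
    slope: float  # log-linear rate regression coefficient on log2 expression
    slope_se: float
    one_sided_p: float  # H1: slope < 0 (prevalence falls with expression)


def expression_prevalence(
    catalog_or_catalogs,
    annotation: GeneAnnotation,
    expression,
    n_bins: int = 8,
) -> ExpressionBinProfile:
    """Expression-binned mutation prevalence with a trend test.

    Genes with expression values are ranked by mean log2 expression into
    ``n_bins`` equal-gene bins; prevalence is mutations per Mb of gene
    footprint per bin.  The trend is a Poisson log-linear regression of
    per-gene mutation counts on log2 expression with log gene length as
    exposure; the one-sided p is for a negative slope.
    """
    import statsmodels.api as sm

    catalogs = (
        catalog_or_catalogs
        if isinstance(catalog_or_catalogs, (list, tuple))
        else [catalog_or_catalogs]
    )
    genes = [g for g in annotation if _has_expression(expression, g.gene_id)]
    if n_bins > len(genes):
        raise ValueError(f"n_bins={n_bins} exceeds {len(genes)} genes with expression")
    counts = {g.gene_id: 0 for g in genes}
    gene_index = {(g.chrom): [] for g in genes}
    for g in genes:
        gene_index[g.chrom].append(g)
    for cat in catalogs:
        for r in cat.substitutions:
            for g in gene_index.get(r.chrom, ()):
                if g.tx_start <= r.pos <= g.tx_end:
                    counts[g.gene_id] += 1
    expr = {g.gene_id: expression.gene_mean(g.gene_id) for g in genes}
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "length": [g.length for g in genes],
            "expression": [expr[g.gene_id] for g in genes],
            "count": [counts[g.gene_id] for g in genes],
        }
    ).sort_values("expression", kind="mergesort", ignore_index=True)
    df["bin"] = pd.qcut(df.index, n_bins, labels=False)
    rows = []
    for b, sub in df.groupby("bin"):
        mb = sub["length"].sum() / 1e6
        rows.append(
            {
                "bin": int(b),
                "mean_log2_expression": sub["expression"].mean(),
                "mutations_per_mb": sub["count"].sum() / mb,
                "gene_count": len(sub),
                "footprint_bp": int(sub["length"].sum()),
            }
        )
    X = sm.add_constant(df["expression"].to_numpy())
    model = sm.GLM(
        df["count"].to_numpy(),
        X,
        family=sm.families.Poisson(),
        offset=np.log(df["length"].to_numpy()),
    )
    fit = model.fit()
    slope, se = float(fit.params[1]), float(fit.bse[1])
    from scipy.stats import norm

    one_sided = float(norm.cdf(slope / se))  # H1: slope < 0
    return ExpressionBinProfile(pd.DataFrame(rows), slope, se, one_sided)


def _has_expression(expression, gene_id: str) -> bool:
    try:
        expression.gene_mean(gene_id)
        return True
    except KeyError:
        return False


@dataclass
class TssProfile:
    coarse: pd.DataFrame  # 1 kb bins to max_dist
    fine: pd.DataFrame  # 100 bp bins within the first coarse bin


def tss_profile(
    catalog_or_catalogs,
    annotation: GeneAnnotation,
    coarse_bin: int = 1000,
    fine_bin: int = 100,
    max_dist: int = 200_000,
) -> TssProfile:
    """Percentage of genes carrying >= 1 mutation per distance bin
    downstream of the TSS (in the direction of transcription).

    Mutations are counted within the gene span on either strand; a gene is
    excluded from a bin's denominator when it is shorter than the bin's far
    edge, so denominators shrink with distance.
    """
    catalogs = (
        catalog_or_catalogs
        if isinstance(catalog_or_catalogs, (list, tuple))
        else [catalog_or_catalogs]
    )
    genes = list(annotation)
    if not genes:
        return TssProfile(pd.DataFrame(), pd.DataFrame())
    # distances downstream of TSS for every (gene, mutation) hit
    dists_per_gene: dict[str, list[int]] = {g.gene_id: [] for g in genes}
    by_chrom: dict[str, list] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for cat in catalogs:
        for r in cat.substitutions:
            for g in by_chrom.get(r.chrom, ()):
                if g.tx_start <= r.pos <= g.tx_end:
                    d = r.pos - g.tss if g.strand == "+" else g.tss - r.pos
                    dists_per_gene[g.gene_id].append(d)

    def profile(bin_size: int, limit: int) -> pd.DataFrame:
        edges = list(range(0, limit, bin_size))
        rows = []
        lengths = {g.gene_id: g.length for g in genes}
        for start in edges:
            far = start + bin_size
            eligible = [g.gene_id for g in genes if lengths[g.gene_id] >= far]
            if not eligible:
                rows.append({"bin_start": start, "bin_end": far, "percent_genes_mutated": np.nan, "n_genes": 0})
                continue
            hit = sum(
                1
                for gid in eligible
                if any(start <= d < far for d in dists_per_gene[gid])
            )
            rows.append(
                {
                    "bin_start": start,
                    "bin_end": far,
                    "percent_genes_mutated": 100.0 * hit / len(eligible),
                    "n_genes": len(eligible),
                }
            )
        return pd.DataFrame(rows)

    return TssProfile(profile(coarse_bin, max_dist), profile(fine_bin, coarse_bin))
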