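"""Synthetic genomes, annotations, and mutation catalogs with known truth.

The generator emulates the study conditions the analysis modules are tested
against: a multi-sample cohort drawn from a mixture of trinucleotide-context
signatures (including an XpCpG C>T deamination-like signature and a TpCpX
C>T/C>G/C>A signature), injected kataegis clusters (TpC-focused, strand
processive, with linked rearrangement breakpoints), adjacent double
substitutions, indels planted in tandem repeats or with junction
microhomology, transcriptional strand bias, and expression-dependent
mutation rates.  Every emitted mutation is traceable to exactly one
generating process in :class:`SyntheticTruth`, and every output is a pure
function of (spec, seed).

The default cohort mirrors a 21-sample whole-genome study: five signatures,
Dirichlet exposures with one sample dominated by a single process, and
2,000-10,000 mutations per sample on a 10 Mb four-chromosome toy genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .catalog import (
    CpGIslandSet,
    ExpressionTable,
    Gene,
    GeneAnnotation,
    IndelRecord,
    MutationCatalog,
    RearrangementRecord,
    ReferenceGenome,
    SubstitutionRecord,
    reverse_complement,
)
from .spectrum import SCHEME

NUCS = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ------------------------------------------------------------- genome

@dataclass
class SyntheticGenomeSpec:
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 2_500_000 for i in range(1, 5)}
    )
    gc: float = 0.5
    n_islands_per_chrom: int = 5
    island_length: int = 2000
    island_cpg_enrichment: float = 10.0
    n_genes: int = 60
    gene_length_range: tuple[int, int] = (20_000, 80_000)
    expression_mean: float = 8.0
    expression_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(l < 10_000 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be >= 10 kb")


@dataclass
class SyntheticGenome:
    genome: ReferenceGenome
    genes: GeneAnnotation
    islands: CpGIslandSet
    gene_expression: dict[str, float]  # per-gene mean log2 expression
    spec: SyntheticGenomeSpec

    @cached_property
    def context_sites(self) -> dict[str, dict[str, np.ndarray]]:
        """Per collapsed pyrimidine-central context, the 1-based positions
        (per chromosome) whose forward-strand window matches the context or
        its reverse complement."""
        from .catalog import _BASE_CODE

        sites: dict[str, dict[str, np.ndarray]] = {}
        for chrom in self.genome.chromosomes:
            seq = self.genome.sequence(chrom)
            codes = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
            five, centre, three = codes[:-2], codes[1:-1], codes[2:]
            valid = (five >= 0) & (centre >= 0) & (three >= 0)
            pur = (centre == 0) | (centre == 2)
            f = np.where(pur, 3 - three, five)
            c = np.where(pur, 3 - centre, centre)
            t = np.where(pur, 3 - five, three)
            idx = f * 16 + c * 4 + t
            pos = np.arange(2, len(seq))  # 1-based centre positions
            for code in np.unique(idx[valid]):
                ctx = NUCS[code // 16] + NUCS[(code // 4) % 4] + NUCS[code % 4]
                sites.setdefault(ctx, {})[chrom] = pos[valid & (idx == code)]
        return sites

    @cached_property
    def context_pools(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Flattened (chrom_index, position) arrays per collapsed context,
        for fast uniform site sampling."""
        chrom_order = self.genome.chromosomes
        pools: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for ctx, per_chrom in self.context_sites.items():
            codes, positions = [], []
            for ci, chrom in enumerate(chrom_order):
                if chrom in per_chrom:
                    arr = per_chrom[chrom]
                    codes.append(np.full(len(arr), ci, dtype=np.int32))
                    positions.append(arr)
            pools[ctx] = (np.concatenate(codes), np.concatenate(positions))
        return pools

    def expression_table(
        self, sample_ids: list[str], seed: int = 0, jitter_sd: float = 0.25
    ) -> ExpressionTable:
        rng = np.random.default_rng(seed)
        values = {}
        for gene_id, base in self.gene_expression.items():
            for sid in sample_ids:
                values[(gene_id, sid)] = base + rng.normal(0, jitter_sd)
        return ExpressionTable(values, self.genes)


def _island_sequence(rng: np.random.Generator, length: int, gc: float, q: float) -> str:
    """CpG-enriched sequence: with probability q emit 'CG', else two i.i.d.
    bases at the background composition."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    out: list[str] = []
    while len(out) < length:
        if rng.random() < q:
            out.extend("CG")
        else:
            out.extend(rng.choice(list(NUCS), size=2, p=p))
    return "".join(out[:length])


def generate_genome(spec: SyntheticGenomeSpec) -> SyntheticGenome:
    rng = np.random.default_rng(spec.seed)
    p = np.array([(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2])
    q = min(0.9, spec.island_cpg_enrichment * 2 * (spec.gc / 2) ** 2)
    seqs: dict[str, str] = {}
    island_list: list[tuple[str, int, int]] = []
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
    for chrom, length in spec.chrom_lengths.items():
        arr = base_bytes[rng.choice(4, size=length, p=p)]
        starts = rng.choice(
            length - spec.island_length, size=spec.n_islands_per_chrom, replace=False
        )
        starts.sort()
        prev_end = -1
        for s in starts:
            if s <= prev_end:
                continue
            isl = _island_sequence(rng, spec.island_length, spec.gc, q)
            arr[s : s + spec.island_length] = np.frombuffer(isl.encode(), dtype=np.uint8)
            island_list.append((chrom, int(s) + 1, int(s) + spec.island_length))
            prev_end = s + spec.island_length
        seqs[chrom] = arr.tobytes().decode()
    genome = ReferenceGenome(seqs)

    total_len = sum(spec.chrom_lengths.values())
    mean_gene = sum(spec.gene_length_range) / 2
    if spec.n_genes * mean_gene > 0.6 * total_len:
        raise ValueError("gene footprint would exceed the genome; reduce n_genes")
    genes: list[Gene] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in spec.chrom_lengths}
    chroms = list(spec.chrom_lengths)
    gi = 0
    attempts = 0
    while gi < spec.n_genes:
        attempts += 1
        if attempts > 100 * spec.n_genes:
            raise ValueError("could not place genes without overlap")
        chrom = chroms[rng.integers(len(chroms))]
        glen = int(rng.integers(*spec.gene_length_range))
        if glen + 2 >= spec.chrom_lengths[chrom]:
            continue
        start = int(rng.integers(1, spec.chrom_lengths[chrom] - glen))
        end = start + glen - 1
        if any(s <= end and start <= e for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(Gene(f"gene_{gi:04d}", chrom, strand, start, end))
        gi += 1
    expression = {
        g.gene_id: float(rng.normal(spec.expression_mean, spec.expression_sd))
        for g in genes
    }
    return SyntheticGenome(
        genome, GeneAnnotation(genes), CpGIslandSet(island_list), expression, spec
    )


# ------------------------------------------------------------- signatures

def default_signature_matrix() -> np.ndarray:
    """Five well-separated 96-channel signatures (columns sum to 1):

    S1  C>T at XpCpG (deamination-like)
    S2  C>T/C>G/C>A at TpCpX (APOBEC-like)
    S3  C>A across all contexts
    S4  T>C across all contexts
    S5  T>G across all contexts
    Each carries a small uniform background so every channel is reachable.
    """
    W = np.zeros((96, 5))
    for i in range(96):
        lab = SCHEME.labels[i]
        cls = SCHEME.substitution_class(i)
        five, three = lab[0], lab[6]
        if cls == "C>T" and three == "G":
            W[i, 0] = 1.0
        if five == "T" and cls in ("C>T", "C>G", "C>A"):
            W[i, 1] = {"C>T": 1.0, "C>G": 0.6, "C>A": 0.2}[cls]
        if cls == "C>A" and five != "T":
            W[i, 2] = 1.0
        if cls == "T>C":
            W[i, 3] = 1.0
        if cls == "T>G":
            W[i, 4] = 1.0
    W = W / W.sum(axis=0)
    background = np.full((96, 5), 1.0 / 96)
    W = 0.97 * W + 0.03 * background
    return W / W.sum(axis=0)


@dataclass
class SignatureMixtureSpec:
    W_true: np.ndarray  # 96 x k, columns sum to 1
    exposures: np.ndarray  # M x k, rows sum to 1
    totals: np.ndarray  # per-sample mutation counts
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if (self.exposures < 0).any():
            raise ValueError("exposures must be nonnegative")
        if not np.allclose(self.exposures.sum(axis=1), 1.0):
            raise ValueError("exposure rows must sum to 1")


def paper_like_mixture(
    seed: int = 0,
    n_samples: int = 21,
    total_range: tuple[int, int] = (2000, 10_000),
    dirichlet_alpha: float = 1.5,
) -> SignatureMixtureSpec:
    """Default cohort: 21 samples over the 5 default signatures, Dirichlet
    exposures with the first sample dominated by the TpCpX signature
    (one process dominant, as seen in heavily mutated genomes)."""
    rng = np.random.default_rng(seed)
    W = default_signature_matrix()
    k = W.shape[1]
    exposures = rng.dirichlet(np.full(k, dirichlet_alpha), size=n_samples)
    dominated = np.full(k, 0.05 / (k - 1))
    dominated[1] = 0.95
    exposures[0] = dominated
    totals = rng.integers(total_range[0], total_range[1] + 1, size=n_samples)
    sample_ids = [f"S{i + 1:02d}" for i in range(n_samples)]
    return SignatureMixtureSpec(W, exposures, totals, sample_ids)


# ------------------------------------------------------------- truth

@dataclass
class SyntheticTruth:
    W_true: np.ndarray | None = None
    exposures: np.ndarray | None = None
    sample_ids: list[str] = field(default_factory=list)
    signature_of: dict[tuple[str, str, int], int] = field(default_factory=dict)
    kataegis_intervals: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    kataegis_members: dict[str, set[tuple[str, int]]] = field(default_factory=dict)
    phases: dict[str, dict[tuple[str, int], str]] = field(default_factory=dict)
    doublet_positions: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    indel_classes: dict[tuple[str, str, int], str] = field(default_factory=dict)
    strand_bias: dict | None = None
    expression_slope: float | None = None


# ------------------------------------------------------------- catalogs

def _draw_channel_counts(
    rng: np.random.Generator, W: np.ndarray, exposure: np.ndarray, total: int
) -> np.ndarray:
    """Per-signature, per-channel counts: totals split multinomially over
    signatures by exposure, then over channels by each signature."""
    k = W.shape[1]
    per_sig = rng.multinomial(total, exposure)
    counts = np.zeros((96, k), dtype=int)
    for s in range(k):
        if per_sig[s]:
            counts[:, s] = rng.multinomial(per_sig[s], W[:, s])
    return counts


def _place_channel_mutations(
    sg: SyntheticGenome,
    rng: np.random.Generator,
    channel_counts: np.ndarray,  # 96 x k
    sample_id: str,
    used: set[tuple[str, int]],
    truth: SyntheticTruth,
) -> list[SubstitutionRecord]:
    records: list[SubstitutionRecord] = []
    by_context: dict[str, list[tuple[int, int, int]]] = {}  # ctx -> (channel, sig, n)
    for i in range(96):
        for s in range(channel_counts.shape[1]):
            n = int(channel_counts[i, s])
            if n:
                by_context.setdefault(SCHEME.context(i), []).append((i, s, n))
    chrom_order = sg.genome.chromosomes
    for ctx, needs in by_context.items():
        if ctx not in sg.context_pools:
            raise ValueError(f"no sites for context {ctx} in the genome")
        chrom_codes, positions = sg.context_pools[ctx]
        pool_size = len(positions)
        need_total = sum(n for _, _, n in needs)
        if need_total > pool_size:
            raise ValueError(f"demand {need_total} exceeds {pool_size} sites for context {ctx}")
        picked: list[tuple[str, int]] = []
        seen_idx: set[int] = set()
        tries = 0
        while len(picked) < need_total:
            tries += 1
            if tries > 200:
                raise ValueError(f"not enough free sites for context {ctx}")
            for j in rng.integers(0, pool_size, size=2 * (need_total - len(picked)) + 8):
                j = int(j)
                if j in seen_idx:
                    continue
                seen_idx.add(j)
                site = (chrom_order[chrom_codes[j]], int(positions[j]))
                if site in used:
                    continue
                picked.append(site)
                used.add(site)
                if len(picked) == need_total:
                    break
        pos_iter = iter(picked)
        for channel, sig, n in needs:
            lab = SCHEME.labels[channel]
            pyr_ref, pyr_alt = lab[2], lab[4]
            for _ in range(n):
                chrom, pos = next(pos_iter)
                fwd = sg.genome.base(chrom, pos)
                if fwd == pyr_ref:
                    ref, alt = pyr_ref, pyr_alt
                else:  # purine presentation (site matched by reverse complement)
                    ref, alt = _COMP[pyr_ref], _COMP[pyr_alt]
                records.append(SubstitutionRecord(sample_id, chrom, pos, ref, alt))
                truth.signature_of[(sample_id, chrom, pos)] = sig
    return records


def simulate_catalog(
    sg: SyntheticGenome,
    mixture: SignatureMixtureSpec,
    sample_index: int,
    seed: int,
    truth: SyntheticTruth | None = None,
) -> tuple[MutationCatalog, SyntheticTruth]:
    """One sample's substitution catalog drawn from the signature mixture.

    Channel counts are multinomial from W_true . exposure; positions are
    uniform among matching context sites without replacement; the purine vs
    pyrimidine forward-strand presentation follows the site drawn (~50/50
    on a GC-balanced genome).
    """
    truth = truth if truth is not None else SyntheticTruth(
        W_true=mixture.W_true, exposures=mixture.exposures, sample_ids=mixture.sample_ids
    )
    rng = np.random.default_rng(seed)
    sid = mixture.sample_ids[sample_index]
    counts = _draw_channel_counts(
        rng, mixture.W_true, mixture.exposures[sample_index], int(mixture.totals[sample_index])
    )
    used: set[tuple[str, int]] = set()
    records = _place_channel_mutations(sg, rng, counts, sid, used, truth)
    return MutationCatalog(sid, records), truth


def simulate_cohort(
    sg: SyntheticGenome, mixture: SignatureMixtureSpec, seed: int = 0
) -> tuple[list[MutationCatalog], SyntheticTruth]:
    truth = SyntheticTruth(
        W_true=mixture.W_true, exposures=mixture.exposures, sample_ids=mixture.sample_ids
    )
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=len(mixture.sample_ids))
    catalogs = []
    for i in range(len(mixture.sample_ids)):
        cat, _ = simulate_catalog(sg, mixture, i, int(seeds[i]), truth)
        catalogs.append(cat)
    return catalogs, truth


# ------------------------------------------------------------- kataegis

@dataclass
class KataegisSpec:
    clusters_per_sample: int = 3
    cluster_size: int = 15
    gap_range: tuple[int, int] = (50, 500)
    class_probs: dict[str, float] = field(
        default_factory=lambda: {"C>T": 0.6, "C>G": 0.3, "C>A": 0.1}
    )
    strand_switch_prob: float = 0.1
    rearrangements_per_cluster: int = 2
    rearrangement_offset: int = 10_000


def _next_tpc_site(
    seq: str, start: int, orientation: str, limit: int = 3000
) -> int | None:
    """Next 1-based position >= start of a TpC cytosine on the requested
    strand: forward = 'TC' (mutate the C), reverse = 'GA' (mutate the G)."""
    pat = "TC" if orientation == "fwd" else "GA"
    i = seq.find(pat, max(start - 2, 0), start + limit)
    if i == -1:
        return None
    return i + 2 if orientation == "fwd" else i + 1


def inject_kataegis(
    catalog: MutationCatalog,
    sg: SyntheticGenome,
    spec: KataegisSpec,
    seed: int,
    truth: SyntheticTruth,
) -> MutationCatalog:
    """Add strand-processive TpC-focused clusters with linked rearrangement
    breakpoints; members carry truth intervals and a shared phase label."""
    rng = np.random.default_rng(seed)
    sid = catalog.sample_id
    used = {(r.chrom, r.pos) for r in catalog.substitutions}
    new_subs: list[SubstitutionRecord] = []
    rearrs: list[RearrangementRecord] = list(catalog.rearrangements)
    intervals = truth.kataegis_intervals.setdefault(sid, [])
    members = truth.kataegis_members.setdefault(sid, set())
    phases = truth.phases.setdefault(sid, {})
    chroms = sg.genome.chromosomes
    classes = list(spec.class_probs)
    probs = np.array([spec.class_probs[c] for c in classes])
    probs = probs / probs.sum()
    for ci in range(spec.clusters_per_sample):
        for _attempt in range(100):
            chrom = chroms[rng.integers(len(chroms))]
            seq = sg.genome.sequence(chrom)
            start = int(rng.integers(10_000, len(seq) - 200_000))
            orientation = "fwd" if rng.random() < 0.5 else "rev"
            positions: list[tuple[int, str, str]] = []  # pos, ref, alt
            pos = start
            ok = True
            for _m in range(spec.cluster_size):
                pos += int(rng.integers(*spec.gap_range))
                if rng.random() < spec.strand_switch_prob:
                    orientation = "rev" if orientation == "fwd" else "fwd"
                site = _next_tpc_site(seq, pos, orientation)
                if site is None or (chrom, site) in used:
                    ok = False
                    break
                cls = classes[int(rng.choice(len(classes), p=probs))]
                pyr_ref, pyr_alt = cls[0], cls[2]
                if orientation == "fwd":
                    ref, alt = pyr_ref, pyr_alt
                else:
                    ref, alt = _COMP[pyr_ref], _COMP[pyr_alt]
                positions.append((site, ref, alt))
                pos = site
            if not ok:
                continue
            for p, ref, alt in positions:
                new_subs.append(SubstitutionRecord(sid, chrom, p, ref, alt))
                used.add((chrom, p))
                members.add((chrom, p))
                phases[(chrom, p)] = f"cluster{ci}_hap1"
            lo, hi = positions[0][0], positions[-1][0]
            intervals.append((chrom, lo, hi))
            for _r in range(spec.rearrangements_per_cluster):
                bp = int(rng.integers(max(lo - spec.rearrangement_offset, 1),
                                      hi + spec.rearrangement_offset))
                partner = int(rng.integers(1, len(seq)))
                rearrs.append(RearrangementRecord(sid, chrom, bp, chrom, partner))
            break
    return MutationCatalog(
        sid,
        list(catalog.substitutions) + new_subs,
        catalog.indels,
        rearrs,
    )


# ---------------------------------------------- positions-only catalogs

_CLASS_REFS = {"C>A": ("C", "A"), "C>G": ("C", "G"), "C>T": ("C", "T"),
               "T>A": ("T", "A"), "T>C": ("T", "C"), "T>G": ("T", "G")}


def simulate_uniform_catalog(
    chrom_lengths: dict[str, int],
    n_mutations: int,
    seed: int,
    sample_id: str = "U1",
    class_probs: dict[str, float] | None = None,
) -> MutationCatalog:
    """Mutations placed uniformly at random (without positional collision)
    across chromosomes, with classes drawn i.i.d.  Positions only — ref/alt
    encode the class and are not tied to any sequence, which suffices for
    rainfall, clustering, and adjacency analyses."""
    from .doublets import sample_unique_positions

    rng = np.random.default_rng(seed)
    if class_probs is None:
        class_probs = {"C>T": 0.4, "C>A": 0.2, "T>C": 0.2, "C>G": 0.1,
                       "T>A": 0.05, "T>G": 0.05}
    classes = list(class_probs)
    probs = np.array([class_probs[c] for c in classes])
    probs = probs / probs.sum()
    total_len = sum(chrom_lengths.values())
    per_chrom = rng.multinomial(
        n_mutations, [l / total_len for l in chrom_lengths.values()]
    )
    records = []
    for (chrom, length), n in zip(chrom_lengths.items(), per_chrom):
        if n == 0:
            continue
        for pos in sample_unique_positions(rng, length, int(n)):
            cls = classes[int(rng.choice(len(classes), p=probs))]
            ref, alt = _CLASS_REFS[cls]
            records.append(SubstitutionRecord(sample_id, chrom, int(pos), ref, alt))
    return MutationCatalog(sample_id, records)


def simulate_adjacency_catalog(
    chrom_lengths: dict[str, int],
    n_total: int,
    n_doublets: int,
    seed: int,
    sample_id: str = "D1",
) -> MutationCatalog:
    """A uniform catalog of ``n_total`` mutations of which ``n_doublets``
    pairs are injected at adjacent positions (each pair counts two
    mutations), the study condition for the adjacency-enrichment test."""
    rng = np.random.default_rng(seed)
    base = simulate_uniform_catalog(
        chrom_lengths, n_total - 2 * n_doublets, seed=int(rng.integers(2**31)),
        sample_id=sample_id,
    )
    used = {(r.chrom, r.pos) for r in base.substitutions}
    chroms = list(chrom_lengths)
    records = list(base.substitutions)
    placed = 0
    while placed < n_doublets:
        chrom = chroms[rng.integers(len(chroms))]
        p = int(rng.integers(2, chrom_lengths[chrom] - 1))
        if any((chrom, q) in used for q in (p - 1, p, p + 1, p + 2)):
            continue
        for q in (p, p + 1):
            cls = ["C>A", "C>T", "T>C"][int(rng.integers(3))]
            ref, alt = _CLASS_REFS[cls]
            records.append(SubstitutionRecord(sample_id, chrom, q, ref, alt))
            used.add((chrom, q))
        placed += 1
    return MutationCatalog(sample_id, records)


# ------------------------------------------------------------- doublets

def inject_doublets(
    catalog: MutationCatalog,
    sg: SyntheticGenome,
    n_doublets: int,
    seed: int,
    truth: SyntheticTruth,
) -> MutationCatalog:
    """Add adjacent same-sample substitution pairs at random loci."""
    rng = np.random.default_rng(seed)
    sid = catalog.sample_id
    used = {(r.chrom, r.pos) for r in catalog.substitutions}
    new_subs: list[SubstitutionRecord] = []
    positions = truth.doublet_positions.setdefault(sid, [])
    chroms = sg.genome.chromosomes
    for _ in range(n_doublets):
        for _attempt in range(100):
            chrom = chroms[rng.integers(len(chroms))]
            seq = sg.genome.sequence(chrom)
            p = int(rng.integers(2, len(seq) - 2))
            if any((chrom, q) in used for q in (p - 1, p, p + 1, p + 2)):
                continue
            pair = []
            for q in (p, p + 1):
                ref = seq[q - 1]
                if ref == "N":
                    break
                alt = NUCS[(NUCS.index(ref) + 1 + rng.integers(3)) % 4]
                pair.append(SubstitutionRecord(sid, chrom, q, ref, alt))
            if len(pair) != 2:
                continue
            new_subs.extend(pair)
            used.update({(chrom, p), (chrom, p + 1)})
            positions.append((chrom, p))
            break
        else:
            raise RuntimeError("could not place doublet after 100 attempts")
    return MutationCatalog(
        sid, list(catalog.substitutions) + new_subs, catalog.indels, catalog.rearrangements
    )


# ------------------------------------------------------------- indels

@dataclass
class IndelSpec:
    n_repeat: int = 30
    n_microhomology: int = 20
    n_none: int = 10
    mh_range: tuple[int, int] = (2, 5)
    repeat_unit_lengths: tuple[int, ...] = (1, 2, 3)
    mh_deletion_length: tuple[int, int] = (6, 20)


def _is_tandem_with_adjacent(seq_del: str, left: str, right: str, max_unit: int = 6) -> bool:
    """Direct check used by the generator: deleted seq is whole copies of a
    unit with one further copy immediately adjacent."""
    for u in range(1, min(max_unit, len(seq_del)) + 1):
        if len(seq_del) % u or seq_del != seq_del[:u] * (len(seq_del) // u):
            continue
        unit = seq_del[:u]
        if right.startswith(unit) or left.endswith(unit):
            return True
    return False


def _junction_mh(seq_del: str, left: str, right: str) -> int:
    pre = 0
    for a, b in zip(seq_del, right):
        if a != b:
            break
        pre += 1
    suf = 0
    for a, b in zip(seq_del[::-1], left[::-1]):
        if a != b:
            break
        suf += 1
    return max(pre, suf)


def inject_indels(
    catalog: MutationCatalog,
    sg: SyntheticGenome,
    spec: IndelSpec,
    seed: int,
    truth: SyntheticTruth,
) -> MutationCatalog:
    """Plant deletions at reference loci whose flanks realize the requested
    architecture, found by direct string scans (independent of the
    classifier): tandem-repeat deletions, junction-microhomology deletions,
    and featureless controls."""
    rng = np.random.default_rng(seed)
    sid = catalog.sample_id
    indels: list[IndelRecord] = list(catalog.indels)
    used: set[tuple[str, int]] = {(r.chrom, r.pos) for r in indels}
    chroms = sg.genome.chromosomes

    def random_locus(margin: int = 200) -> tuple[str, str, int]:
        chrom = chroms[rng.integers(len(chroms))]
        seq = sg.genome.sequence(chrom)
        p = int(rng.integers(margin, len(seq) - margin))
        return chrom, seq, p

    def add(chrom: str, pos: int, seq_del: str, klass: str) -> None:
        rec = IndelRecord(sid, chrom, pos, "deletion", seq_del, len(seq_del))
        indels.append(rec)
        used.add((chrom, pos))
        truth.indel_classes[(sid, chrom, pos)] = klass

    placed = 0
    guard = 0
    while placed < spec.n_repeat:
        guard += 1
        if guard > 50_000:
            raise RuntimeError("could not place repeat indels")
        chrom, seq, p = random_locus()
        u = int(rng.choice(spec.repeat_unit_lengths))
        seq_del = seq[p : p + u]  # deletes positions p+1..p+u (0-based slice)
        if "N" in seq_del or (chrom, p) in used:
            continue
        nxt = seq[p + u : p + 2 * u]
        if nxt == seq_del and len(nxt) == u:  # adjacent 3' copy
            add(chrom, p, seq_del, "repeat")
            placed += 1

    placed = 0
    guard = 0
    while placed < spec.n_microhomology:
        guard += 1
        if guard > 200_000:
            raise RuntimeError("could not place microhomology indels")
        chrom, seq, p = random_locus()
        L = int(rng.integers(*spec.mh_deletion_length))
        seq_del = seq[p : p + L]
        left = seq[max(p - 50, 0) : p]
        right = seq[p + L : p + L + 50]
        if "N" in seq_del or (chrom, p) in used:
            continue
        mh = _junction_mh(seq_del, left, right)
        if spec.mh_range[0] <= mh <= spec.mh_range[1] and not _is_tandem_with_adjacent(
            seq_del, left, right
        ):
            add(chrom, p, seq_del, "microhomology")
            placed += 1

    placed = 0
    guard = 0
    while placed < spec.n_none:
        guard += 1
        if guard > 200_000:
            raise RuntimeError("could not place featureless indels")
        chrom, seq, p = random_locus()
        L = int(rng.integers(1, 11))
        seq_del = seq[p : p + L]
        left = seq[max(p - 50, 0) : p]
        right = seq[p + L : p + L + 50]
        if "N" in seq_del or (chrom, p) in used:
            continue
        if _junction_mh(seq_del, left, right) < 2 and not _is_tandem_with_adjacent(
            seq_del, left, right
        ):
            add(chrom, p, seq_del, "none")
            placed += 1

    return MutationCatalog(sid, catalog.substitutions, indels, catalog.rearrangements)


# ----------------------------------------------------- CpG deamination

def simulate_cpg_catalog(
    sg: SyntheticGenome,
    sample_id: str,
    rate_outside: float,
    in_island_factor: float,
    seed: int,
) -> MutationCatalog:
    """C>T deamination at CpG sites: each at-risk cytosine (either strand)
    mutates independently at ``rate_outside`` outside islands and
    ``rate_outside / in_island_factor`` inside (methylated CpGs deaminate;
    island CpGs are mostly unmethylated, hence the lower in-island rate)."""
    from .spectrum import cpg_site_positions

    rng = np.random.default_rng(seed)
    outside, inside = cpg_site_positions(sg.genome, sg.islands)
    records = []
    seen: set[tuple[str, int]] = set()
    for sites, rate in ((outside, rate_outside), (inside, rate_outside / in_island_factor)):
        hits = np.nonzero(rng.random(len(sites)) < rate)[0]
        for j in hits:
            chrom, pos, base = sites[j]
            if (chrom, pos) in seen:
                continue
            seen.add((chrom, pos))
            ref, alt = ("C", "T") if base == "C" else ("G", "A")
            records.append(SubstitutionRecord(sample_id, chrom, pos, ref, alt))
    return MutationCatalog(sample_id, records)


# ------------------------------------------------ transcription effects

def apply_strand_bias(
    catalog: MutationCatalog,
    sg: SyntheticGenome,
    mut_class: str,
    untranscribed_to_transcribed: float,
    seed: int,
    truth: SyntheticTruth,
) -> MutationCatalog:
    """Thin transcribed-strand mutations of one class inside gene bodies so
    the untranscribed:transcribed ratio approaches the requested value."""
    from .transcription import assign_strand

    rng = np.random.default_rng(seed)
    keep_prob = 1.0 / untranscribed_to_transcribed
    kept = []
    for r in catalog.substitutions:
        a = assign_strand(r, sg.genes)
        if (
            a.mut_class == mut_class
            and a.assignment == "transcribed"
            and rng.random() > keep_prob
        ):
            continue
        kept.append(r)
    truth.strand_bias = {"class": mut_class, "ratio": untranscribed_to_transcribed}
    return MutationCatalog(
        catalog.sample_id, kept, catalog.indels, catalog.rearrangements
    )


def apply_expression_effect(
    catalog: MutationCatalog,
    sg: SyntheticGenome,
    slope_per_log2: float,
    seed: int,
    truth: SyntheticTruth,
) -> MutationCatalog:
    """Thin gene-body mutations so the retention rate scales as
    exp(slope_per_log2 * log2 expression); slope < 0 suppresses mutations in
    highly expressed genes."""
    rng = np.random.default_rng(seed)
    exprs = sg.gene_expression
    max_val = max(np.exp(slope_per_log2 * e) for e in exprs.values())
    kept = []
    for r in catalog.substitutions:
        genes = sg.genes.overlapping(r.chrom, r.pos)
        if genes:
            e = exprs[genes[0].gene_id]
            if rng.random() > np.exp(slope_per_log2 * e) / max_val:
                continue
        kept.append(r)
    truth.expression_slope = slope_per_log2
    return MutationCatalog(
        catalog.sample_id, kept, catalog.indels, catalog.rearrangements
    )
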