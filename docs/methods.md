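# Methods

`mutforge` analyzes per-sample somatic mutation catalogs for the imprints
of mutational processes.  This note documents the models and procedures,
their tunable parameters, the synthetic-data generator the test suite is
built on, and the numerical choices made where the design was open.

## 96-channel mutation spectra

Every single-base substitution is reduced to a pyrimidine reference: a
mutated purine is reverse-complemented together with its flanking bases, so
the six substitution classes are C>A, C>G, C>T, T>A, T>C, T>G, and with 16
possible 5'/3' flanking combinations there are 6 × 16 = 96 mutated
trinucleotide channels.  Channel order is fixed (classes in the order
above, contexts lexicographic in 5' then 3' base), making all serialized
matrices deterministic.  Substitutions whose trinucleotide window falls off
a chromosome end or contains N are excluded from spectra, and N-containing
windows are likewise excluded from the genome's context-occurrence table,
so count-per-occurrence rates remain well defined.

The heatmap representation is `log(count / genome occurrences of the
channel's context)` per sample.  Zero-count cells are masked (`NA`), never
−∞.  Multiplying all context occurrences by a constant shifts every
unmasked value by the same additive constant.

**CpG-island odds ratio.**  C>T events at CpG dinucleotides report
deamination of methylated cytosine.  The at-risk denominator is the set of
cytosines within CpG dinucleotides on either strand (both the C and the G
position of every CG occurrence), partitioned inside/outside islands.  The
odds ratio is oriented outside/inside (OR > 1 = higher rate outside
islands, where CpGs are mostly methylated), with a Woolf 95% log-interval:
`exp(log OR ± 1.96·√(Σ 1/cell))`.  Any zero cell leaves the CI undefined
rather than applying a silent continuity correction.  The interval is
asymptotic; its coverage is verified by simulation at per-site rates small
enough (≈0.005 and below) that odds and rates coincide.

## Signature extraction by NMF

The 96 × M count matrix A (raw counts, not context-corrected; correction is
display-only) is factorized as A ≈ W·H with W ≥ 0 (96 × k signatures) and
H ≥ 0 (k × M exposures) by Lee–Seung multiplicative updates minimizing
½‖A − WH‖²_F.  Implementation choices:

- Initialization: i.i.d. uniform(0, 1] entries scaled by mean(A), seeded
  per restart.  Denominators are guarded by ε = 1e−12, so all-zero rows of
  A are tolerated.
- Stopping: relative change of the Frobenius error < `tol` (default 1e−6)
  or `max_iter` (default 2000).  The error trajectory is recorded; it is
  non-increasing up to machine precision.
- Rank selection: for each k in the scanned range, `n_runs` seeded restarts
  (default 100, configurable to 1000).  Each run assigns every sample to
  its maximal-exposure signature; co-assignment frequencies over runs form
  an M × M consensus matrix; the cophenetic correlation between consensus
  distances (1 − C) and the cophenetic distances of their average-linkage
  dendrogram measures stability (1 = perfectly reproducible).

**Choosing k.**  The stable ranks are the leading run with cophenetic
≥ 0.95; an isolated single-rank dip below the threshold is treated as
consensus noise (stability must be lost at two consecutive ranks to end the
run).  Within the stable run, k is put at the elbow of the mean
reconstruction-error curve.  An elbow is *marked* only when the incoming
error drop e(k−1) − e(k) both exceeds the outgoing drop e(k) − e(k+1) by a
factor ≥ 2 and amounts to ≥ 5% of the error range over the scanned ranks;
the chosen k is the largest marked elbow, falling back to the smallest
stable rank when no elbow qualifies.  Both qualifiers matter: ranks just
past the true one absorb noise in steps whose ratios occasionally exceed 2
but whose magnitudes are small, while a pure magnitude criterion favors the
steep early part of the curve.  With this rule the default synthetic cohort
(below) recovers k = 5 in 10/10 seeded replicates.

Extracted signatures come from the best-error restart; W columns are
normalized to sum 1 with H rescaled inversely, so exposures are in mutation
counts (and per-sample proportions).  Known sequencing-artifact channels
can be excluded via a user-supplied blocklist before factorization; no
automatic artifact detection is attempted.  Samples are clustered by
average-linkage hierarchical clustering on Euclidean distances between
exposure-proportion vectors.

## Kataegis

Intermutation distance (IMD) is the distance from each substitution to the
previous one on the same chromosome; the first mutation per chromosome has
undefined IMD.  Since the source phenomenon was identified visually from
rainfall plots, the caller uses an explicit operational rule, with every
threshold exposed and echoed into output metadata:

| parameter | default | meaning |
|---|---|---|
| `min_cluster_size` | 6 | minimum mutations per microcluster |
| `imd_threshold` | 1,000 bp | maximum successive IMD inside a cluster |
| `macro_gap` | 1 Mb | maximum gap when merging clusters into macroclusters |

Clusters are maximal runs (extending either end violates a threshold) and
non-overlapping by construction.  Per cluster the caller reports the
strand-collapsed ±10 bp flank composition of C>X members, the TpC fraction
(5' T), and C>T / C>G fractions.  Processivity is summarized as maximal
runs of identical forward-strand changes (C>T distinct from G>A).
Mutation phase is consumed as an optional per-mutation annotation (e.g.
from the generator, or an upstream read-based phaser), never inferred.
Rearrangement colocalization reports each cluster's nearest-breakpoint
distance and, per macrocluster, breakpoint counts inside vs the rest of the
chromosome with per-Mb rates and a one-sided binomial enrichment p using
region length as exposure.

## Double substitutions

Maximal runs of consecutive substituted positions partition a catalog into
singletons, doublets (runs of exactly 2), and complex runs (≥ 3, excluded
from doublet counts).  Doublets collapse by reverse complement into 78
canonical classes.  The Monte Carlo enrichment test preserves the observed
per-chromosome, per-class mutation counts and re-places every mutation
uniformly (without positional collision, which is negligible at genomic
densities but enforced); trinucleotide composition is deliberately ignored,
matching a null of independently scattered substitutions.  The empirical
p-value uses the add-one convention (1 + #{sims ≥ observed})/(n_sims + 1),
so the attainable floor at 1,000 simulations is 1/1001 < 0.001 and p is
never exactly 0.

## Transcription-coupled effects

With the mutated pyrimidine on the forward strand, a gene transcribed from
the + strand places the pyrimidine on the untranscribed (coding) strand;
the assignment flips for − strand genes and for reverse-strand pyrimidines.
Positions covered by genes on both strands are ambiguous and excluded;
gene footprints are transcript spans (tx_start..tx_end), nested genes
resolve to the longest transcript.  Strand bias per class pair is a
two-sided exact binomial test of the transcribed count against an expected
proportion computed from the at-risk pyrimidine content of each strand
within gene footprints (≈ 0.5 on a GC-balanced genome, but computed, not
assumed).  Expression-binned prevalence ranks genes into equal-gene bins by
mean log2 expression and reports mutations per Mb of footprint; the trend
statistic is a Poisson log-linear regression of per-gene counts on log2
expression with log gene length as offset (one-sided p for a negative
slope).  TSS profiles report the percentage of genes with ≥ 1 mutation per
distance bin downstream of the TSS (1 kb bins to 200 kb; 100 bp bins within
the first kb); genes shorter than a bin's far edge leave that bin's
denominator, and all substitutions are counted regardless of strand.

## Indel architecture

Classification precedence is repeat → microhomology → none, total and
deterministic:

- **Repeat**: the indel sequence is a whole number of copies of a unit of
  ≤ `max_unit` (default 6) bp and at least one further whole unit lies
  immediately adjacent in the reference (replication slippage).  Both
  deletions and insertions are eligible.
- **Microhomology** (deletions only): junction identity measured as the
  longest prefix of the deleted sequence matching the sequence immediately
  3' of the deletion, or the longest suffix matching the 5' flank,
  whichever is greater; class assigned when ≥ `mh_min` (default 2 bp,
  since 1 bp matches arise at ~44% of junctions by chance).

The chance expectation for junction microhomology uses the per-position
match probability p = Σ_b p_b² from flank base composition:
P(run ≥ j per side) = pʲ, capped at the deletion length and combined
across both sides as the maximum.  The formula is exact under uniform
composition and a close approximation otherwise (the two sides share the
deleted sequence, which induces mild dependence for very short deletions).
Expected counts are accumulated per deletion so they sum to the number of
deletions analyzed; the chi-square summary pools tail bins to expected ≥ 5.
Length distributions of repeat- vs microhomology-mediated indels are
compared by a two-sample Kolmogorov–Smirnov test; group differences in MH
fraction (e.g. homologous-recombination-deficient vs sporadic samples) by
Fisher's exact test.

## Synthetic-data generator

The generator is first-class, tested code; it defines the conditions every
recovery and calibration test runs under.

- **Genome**: 10 Mb over four chromosomes by default, i.i.d. bases at GC
  0.5; 5 CpG islands of 2 kb per chromosome built by a paired-emission
  process (emit "CG" with probability q, else two background bases), giving
  ~10× CpG enrichment; 60 non-overlapping genes of 20–80 kb with random
  strand; per-gene log2 expression ~ Normal(8, 2).  Every output is a pure
  function of (spec, seed).
- **Signature cohort**: 21 samples, five well-separated signatures —
  XpCpG-restricted C>T (deamination-like), TpCpX C>T/C>G/C>A
  (APOBEC-like), broad C>A, broad T>C, broad T>G — each with 3% uniform
  background mass; Dirichlet(1.5) exposures with sample 1 dominated (95%)
  by the TpCpX process; 2,000–10,000 mutations per sample.  Channel counts
  are drawn hierarchically (multinomial over signatures by exposure, then
  over channels by signature), positions uniformly among matching context
  sites without replacement, with the strand presentation following the
  site drawn.  Per-mutation signature attribution is recorded as truth.
- **Kataegis**: clusters of 15 TpC-focused mutations (C>T 0.6 / C>G 0.3 /
  C>A 0.1), gaps uniform 50–500 bp (span ≈ 5 kb), strand switch probability
  0.1 per step, two linked intrachromosomal breakpoints within 10 kb;
  members carry truth intervals and a shared phase label.
- **Doublets / indels**: adjacent pairs at random loci; deletions planted
  at reference loci found by direct string scans (independent of the
  classifier) realizing tandem-repeat, junction-microhomology (mh 2–5,
  lengths 6–20), or featureless architecture.
- **Transcription effects**: strand bias and expression dependence injected
  by rejection thinning of gene-body mutations.

What the generator does *not* emulate: chromatin/replication-timing rate
covariates, mutation clustering beyond injected kataegis, realistic human
trinucleotide composition, read-level evidence.  Passing tests therefore
demonstrate correctness of the statistical machinery under its stated
model, not robustness to every property of real tumor genomes.

## Problem sizes and tolerances

The test suite runs recovery at reduced scale chosen as the smallest sizes
at which the statistical claims are sharp: rank selection on 96 × 21
matrices with 100 restarts per rank; calibration loops at 100–200 seeds;
Monte Carlo checks at 500–50,000 draws.  Null-calibration KS bounds allow
for the conservativeness of discrete test statistics (add-one empirical p,
exact binomial).  Comparisons against closed forms use absolute tolerances
of 1e−9 to 1e−12; recovery assertions (cosine ≥ 0.9, accuracy ≥ 0.95,
recall/precision ≥ 0.95) follow the stated study conditions.

## Known limitations

- The chosen-k rule's two elbow qualifiers (ratio 2, 5% of range) are
  calibrated for cohorts whose error curve flattens after the true rank;
  data with genuinely gradual structure (e.g. many weak signatures) may
  select conservatively small k.
- The Woolf CI for the CpG-island OR is asymptotic; with fewer than ~10
  in-island events the zero-cell flag, not the interval, is the honest
  output.
- The microhomology chance model treats junction sides as independent;
  for 1 bp deletions under skewed composition this is only approximate.
- Kataegis calling is threshold-based; clusters of fewer than 6 mutations
  or with internal gaps > 1 kb are split or missed by design.
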