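# Methods

This note documents the models, numerical choices and known limitations of
`fhsig`, in the order the pipeline runs.

## Synthetic study design

The generators define the conditions every claim in this package is tested
under. The bulk design mirrors a sorted-population infection study: five
infection models (LCMV, influenza, *T. muris*, *H. polygyrus*,
*C. rodentium*) × four CD4⁺ populations (IL-21⁺ T_FH, IL-21⁻ T_FH, T_FR,
T_eff) × 3 replicates, 5,000 genes. Counts are negative binomial with
variance μ + φμ² (φ = 0.1, a typical bulk RNA-seq overdispersion); library
sizes are lognormal with mean 2×10⁷ reads and CV 0.3, desk-scale but above
the <1 M-read exclusion filter. Planted categories: 200 core-up and 200
core-down genes (shifted ±1.5 log₂ units in both T_FH subsets vs T_eff in
every condition), 100 follicular-shared genes (up in T_FH *and* T_FR), and
100 pathogen-specific genes per condition (up in that condition's T_FH only).

Two deliberate consequences of this design:

* Follicular-shared genes satisfy the core rule by construction (they are
  differential in T_FH vs T_eff everywhere), so recovery is measured against
  core-up ∪ follicular-shared for the up direction
  (`SyntheticTruth.expected_core`). They are exactly the genes the four-group
  partition labels "core, co-expressed in T_FR" (group 2).
* No T_FR-*exclusive* category is planted, so the dual-contrast T_FR rule is
  correctly empty on synthetic defaults; it is unit-tested on constructed
  call sets instead.

The mean model multiplies a fixed per-gene baseline (log₂-normal) by the
planted shifts and a per-sample library size against a *constant*
normalizer, so analytic μ-ratios between matched samples equal 2^lfc exactly
— testable on the μ matrix without sampling noise. A side effect worth
knowing: realized totals drift slightly from the drawn library sizes, and
plain CPM carries a small composition bias on planted genes (≈ −0.16 log₂ at
these settings); TMM absorbs most of it, which is the point of TMM.

The gene→category map is drawn from an RNG stream that depends only on
(seed, design counts), so bulk, single-cell and spatial datasets generated
from matching configs share the same planted truth, and bulk-derived
signatures project meaningfully onto the other modalities.

The single-cell layer is Poisson around per-cell scaled cluster means (3
clusters × 200 cells, 3 donors, ~5,000 counts/cell): cluster 0 carries the
core-up program, clusters k > 0 the k-th pathogen program, all at the same
planted effect. 2% of genes are mitochondrial (`mt-` prefix, elevated
baseline) and 5% of cells get a ~50× mito boost to exercise the ≥ 20% QC
filter. The spatial layer reuses this machinery with one cell per grid point
and circular GC-like regions expressing the core program. Not emulated:
gene-length/GC bias, batch effects, ambient RNA, doublets, donor-specific
expression shifts, realistic spatial morphology. Passing tests therefore
demonstrate correctness of the *rules and statistics* under the assumed
noise model, not robustness to those artefacts.

## Differential expression engine

* **Filters.** Technical replicates are summed first. Samples under 10⁶
  reads are dropped (strict `<`). Genes are kept iff CPM ≥
  min_count/(median library in millions) in at least as many samples as the
  smallest group holds, and total count ≥ min_total (defaults 10 and 15, the
  published convention for this filter; the parameters are configurable).
* **TMM.** Reference = sample whose upper-quartile/library ratio is closest
  to the mean of those. M and A are computed over genes positive in both
  samples, doubly trimmed (30% per M-tail, 5% per A-tail, rank-based with
  `floor(n·trim)+1` cut points), and averaged with inverse delta-method
  variances; factors are rescaled to geometric mean 1. A sample whose M
  values are all within 1e-6 of zero gets factor 1 (exact scaling). The
  implementation agrees with an independent loop-based oracle to 1e-12 and
  with the reference R implementation to printed precision.
* **log-CPM.** log₂((y + p)/(L + 2p)·10⁶) with prior p = 0.5 and effective
  library L = column sum × factor — the closed-form variant, hand-checkable.
* **Precision weights.** sqrt(residual sd) from an ordinary per-gene fit is
  smoothed against mean log-CPM by lowess (span 0.5); the trend is evaluated
  at fitted values (linear interpolation, edge-clamped, floored at 1e-4) and
  weights are predicted sd⁻⁴.
* **Moderation.** Method-of-moments on log s²_g via the digamma/trigamma
  identities; the trigamma inverse is solved by Newton iteration. d₀ is
  capped at 10⁶ (standing in for ∞: complete shrinkage); d₀ = 0 reproduces
  the ordinary t exactly.
* **Thresholded test.** τ = log₂(fold-change threshold); p combines the two
  one-sided tails at d₀ + d_g df. At τ = 0 this is the two-sided moderated
  t; at |log₂FC| = τ, p ≥ 0.5. The reported t is sign(b)·(|b|−τ)/se.
* **Calls.** BH step-up (cumulative minimum), boundary-inclusive at
  q ≤ 0.05, direction = sign of log₂FC.

Designs are group-means (one indicator per group) with optional
treatment-coded covariates; contrasts are mean(numerator) −
mean(denominator). The combined T_FH-vs-T_eff contrast averages the
celltype effect over infections within one condition×celltype model; the
IL-21⁺/IL-21⁻ subsets are pooled by default (configurable), since the rule
concerns T_FH as a class.

## Signature rules

Pure set logic on the {−1, 0, +1} call vectors. "Occurring in three or more
infections" requires the *same direction* in ≥ 3 conditions, and the
combined contrast must share that direction. The T_FR rule applies the same
per-condition consensus to each contrast family before intersecting —
chosen for symmetry with the core rule; a pooled-model alternative would be
a one-line change in the workflow. Genes may belong to several pathogen
signatures (one-vs-rest contrasts are not exclusive); provenance records
the multiplicity. The four-group core partition uses the T_FR-vs-T_eff
consensus call: +1 means "co-expressed in T_FR", and a −1 call groups with
"not co-expressed". Annotation sets (cell-surface, transcriptional
regulators, Bcl-6 network lists) are taken as GMT inputs, never hard-coded.

## Rank scoring

Average-tie ranks; up-score = (mean rank − (n+1)/2) / ((2N−n+1)/2 − (n+1)/2)
− 0.5; down sets use reversed ranks; bidirectional total = up + down. The
±0.5 bounds are attained exactly only by extreme tie-free orderings (ties
across the boundary dilute the mean rank). Signature genes absent from a
dataset are dropped with one warning per signature and the bounds
recomputed on the present subset — chosen over treat-as-bottom because
projection targets (imaging panels in particular) have restricted gene
universes where absent ≠ unexpressed. A coverage guard in the projection
layer errors below 25% panel coverage. "Normalized to the first time point"
is subtraction by default; a guarded ratio mode exists because a ratio of
scores that can be ≤ 0 is not generally meaningful.

## Enrichment

Classic weighted running-sum walk (hit increment |stat|^p/Σ|stat|^p, miss
decrement 1/(N−n_set)), weight p = 1 by default with p = 0 exposed for
hand-checkable tests; an exact |max|/|min| tie returns the positive
extremum. The null permutes *gene sets* (same size, uniformly), matching
the preranked setting: p = (1+hits)/(1+n_perm) Monte-Carlo, or the exact
tail fraction when C(N, n_set) ≤ 10,000 and the null can be enumerated.
NES = ES / mean |null ES| of matching sign — a declared convention; the
one-sided sign-matched p lives on (0, 0.5] under the null (2p is uniform).
The competitive rotation test used for single-cell gene sets elsewhere is
deliberately not reimplemented; the same permutation machinery applied to
the pseudobulk contrast statistic is the documented substitution. BH across
sets reuses the engine's implementation bit-for-bit.

## Single-cell stage

QC removes cells with mito fraction ≥ 20% (inclusive) or totals/detected
genes strictly below the 10th percentile (type-7 linear-interpolation
quantile). Size factors are cell total / median total (a closed-form,
testable substitution for pooling-deconvolution factors — a known
divergence on data with strong composition effects). HVGs are top-variance
with deterministic gene-id tie-break; PCA is gene-centered SVD with the
largest-|loading|-positive sign convention; the kNN graph joins mutual and
one-way neighbours with Jaccard weights over self-excluded k-neighbour
sets (zero-weight edges dropped); Louvain is multi-level modularity with a
seeded RNG, resolution 1.0 by default (cluster *count* is not a claim —
only recovery of planted structure is asserted). Pseudobulk sums are exact
integer sums per (cluster, sample) with groups under 10 cells removed.
Pseudobulk DE runs the bulk engine with donor as a fixed-effect covariate —
a documented substitution for the random-effect consensus-correlation
approach; it errors when donor aliases the contrast. Protein tags get a
per-cell centered log-ratio transform (natural log, pseudocount 1).

## Projection

Pseudobulk → low-expression filter → TMM → log-CPM → rank score on
upregulated signature genes (the projection default; bidirectional behind a
flag), then group means and a dominance table (argmax signature, margin,
ties flagged). T_FH-like cell selection on restricted panels keeps cells
with strictly positive bidirectional core score, optionally within an
annotation whitelist. The 10-cell pseudobulk cutoff is the package default
for a stated 10–30 range; per-run configurable.

## Benchmark sizes and determinism

The self-evaluation (`fhsig.evaluate`, `scripts/acceptance.py`) uses the
full default bulk design for recovery and dominance (ten seeds for the
latter, scoring held-out replicates resampled from the same planted truth),
20 null replicates of a one-condition design at 2,000 genes for error
control, a 1,500-gene three-cluster dataset for the single-cell chain, and
a 30×30 grid with three regions for the spatial contrast — sizes chosen so
the whole benchmark completes in minutes on one CPU while keeping
Monte-Carlo noise well inside the asserted margins. All stages are
deterministic given seeds: NumPy `default_rng` streams keyed per stage, a
seeded igraph RNG for Louvain, and mergesort-stable orderings wherever
ranks are taken.

## Known limitations

* Missing values are unsupported; genes must be complete after filtering.
* The donor fixed effect consumes degrees of freedom and can be infeasible
  with very few pseudosamples per donor, where the random-effect approach
  it replaces would borrow strength.
* The empty-by-design T_FR signature on synthetic data means end-to-end
  T_FR recovery is untested; the rule itself is covered by unit tests.
* Permutation GSEA p-values are bounded below by 1/(1+n_perm); no adaptive
  refinement is implemented.
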