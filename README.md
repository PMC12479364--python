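# fhsig — consensus T_FH signature derivation and rank-based projection

Follicular helper T cells (T_FH) drive germinal center antibody responses, but
any single infection model yields a gene signature entangled with that
pathogen's effector program. `fhsig` implements the multi-condition workflow
that separates the two: derive a **core T_FH signature** as the differential
expression shared across several infection models, derive **pathogen-specific
T_FH signatures** from one-vs-rest contrasts between infections, and project
both onto new bulk, pseudobulked single-cell, or spatial expression data with
a rank-based single-sample score.

The package is organised as an analysis project: the numbered drivers under
`analysis/` tell the story on synthetic data with planted ground truth, and
every computational step lives in the library under `src/fhsig/` where the
tests exercise it.

## The statistics at the core

**Differential expression engine** (`fhsig.bulk_de`). For gene *g*, log-CPM
values (TMM-normalized effective library sizes) are fit by weighted least
squares against a design matrix X, with precision weights from a lowess
mean–variance trend. Residual variances are shrunk by empirical Bayes:

    s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g)

with (d₀, s₀²) estimated by method of moments on log s²_g. Significance uses a
fold-change-thresholded moderated t (null: |log₂FC| ≤ τ, τ = log₂ 1.1 by
default), combining the one-sided tails P(T ≥ (|b|−τ)/se) + P(T ≥ (|b|+τ)/se)
with T ~ t(d₀+d_g), then Benjamini–Hochberg FDR and directional calls
D ∈ {−1, 0, +1} at q ≤ 0.05.

**Signature rules** (`fhsig.signatures`). Core: same-direction calls in ≥ 3 of
5 infections *and* in the combined all-infection contrast. T_FR: consensus
calls agreeing in direction between T_FR-vs-T_FH and T_FR-vs-T_eff.
Pathogen-specific: one-vs-rest calls per infection, split into shared /
T_FH-unique / T_eff-unique, exporting shared ∪ T_FH-unique per pathogen.

**Rank score** (`fhsig.rank_scoring`). Within one sample, genes get average-tie
ascending ranks; a signature's score is its genes' mean rank, min–max
normalized by the analytic extremes and centered, landing in [−0.5, +0.5]
(up-set only) or [−1, +1] (up + reversed-rank down set). The score is exactly
invariant under monotone transforms of expression, which is what makes it
portable across platforms and restricted panels.

Supporting stages: preranked permutation GSEA with exhaustive small-set
enumeration (`fhsig.enrichment`), single-cell QC → log-normalization → PCA →
kNN-Jaccard Louvain clustering → pseudobulk DE with a donor covariate
(`fhsig.sc_pipeline`), and projection/dominance summaries (`fhsig.projection`).
`fhsig.synthetic` generates all three data modalities with planted truth.

## Worked example

```sh
python analysis/01_simulate.py
python analysis/02_bulk_de.py
python analysis/03_derive_signatures.py
python analysis/05_single_cell.py
python analysis/06_project.py
```

The derivation step prints (seed 1, default design: 5 infections × 4 sorted
populations × 3 replicates, 5,000 genes, planted log₂FC 1.5, NB dispersion 0.1):

```
core: 299 up, 199 down
lcmv_tfh_specific: 100 up, 11 down
...
core precision 1.000, recall 0.996; context recall (min over infections) 1.000
```

i.e. the consensus rule recovers essentially every planted core gene (200
core-up + 100 follicular-shared + 200 core-down) with no false positives, and
each pathogen-specific signature recovers its 100 planted genes. The
single-cell and projection steps then print:

```
Louvain: 3 clusters, ARI vs planted = 1.000, modularity = 0.661
held-out bulk: matching infection scores highest in 5/5 conditions
spatial: mean core-up score 0.126 inside GC-like regions vs 0.003 in background
10-seed dominance benchmark: fraction = 1.00 (min per seed 1.00)
```

— the planted clusters are recovered exactly, and on held-out replicates each
infection's pseudobulk scores highest on its own derived signature (diagonal
dominance), the behaviour that justifies projecting such signatures onto
external human datasets.

A `fhsig` command-line interface wraps the same stages
(`fhsig simulate|derive-signatures|score|gsea|cluster|project|report
--config cfg.yaml`), with per-stage provenance records.

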