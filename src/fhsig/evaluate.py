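"""Benchmark evaluations of the pipeline on its own synthetic experiments.

Every function regenerates data from a seed, runs the relevant pipeline
stage, and measures recovery against the planted truth.  These are the
quantitative claims the package makes about itself: signature recovery,
false-discovery control on null data, clustering recovery, pseudobulk DE
power, and held-out projection dominance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import bulk_de, rank_scoring, sc_pipeline, synthetic, workflow
from .config import SimulationConfig
from .io import CountMatrix
from .signatures import GeneSignature
from .synthetic import SyntheticTruth

__all__ = [
    "core_recovery_metrics",
    "bulk_recovery",
    "null_false_call_rate",
    "sc_recovery",
    "projection_dominance",
    "region_separation",
]


def core_recovery_metrics(
    signatures: dict[str, GeneSignature],
    truth: SyntheticTruth,
    conditions,
) -> dict[str, float]:
    """Precision/recall of the derived core and context signatures vs truth."""
    exp_up, exp_down = truth.expected_core()
    up, down = set(signatures["core"].up), set(signatures["core"].down)
    tp = len(up & exp_up) + len(down & exp_down)
    precision = tp / max(len(up) + len(down), 1)
    recall = tp / (len(exp_up) + len(exp_down))

    context_recalls = {}
    for cond in conditions:
        planted = set(truth.specific(cond))
        called = set(signatures[f"{cond}_tfh_specific"].up)
        context_recalls[cond] = len(called & planted) / len(planted) if planted else 1.0
    return {
        "core_precision": precision,
        "core_recall": recall,
        "context_recall_min": min(context_recalls.values()),
        "context_recall_mean": float(np.mean(list(context_recalls.values()))),
        "n_core_up": len(up),
        "n_core_down": len(down),
    }


def bulk_recovery(seed: int = 1) -> dict[str, float]:
    """Full default bulk simulation -> derivation -> recovery metrics."""
    cfg = SimulationConfig(seed=seed)
    counts, meta, truth = synthetic.generate_bulk_experiment(cfg)
    sigs, _ = workflow.derive_from_counts(counts, meta)
    return core_recovery_metrics(sigs, truth, cfg.conditions)


def null_false_call_rate(
    seed: int = 0,
    n_reps: int = 20,
    n_genes: int = 2000,
    fc_threshold: float = 1.1,
    fdr: float = 0.05,
) -> dict[str, float]:
    """Pooled fraction of genes called DE on simulations with no planted effect."""
    called = total = 0
    per_rep = []
    for rep in range(n_reps):
        cfg = SimulationConfig(
            seed=seed * 1000 + rep,
            n_genes=n_genes,
            effect_lfc=0.0,
            conditions=("a",),
            n_core_up=0,
            n_core_down=0,
            n_tfr_shared=0,
            n_specific_per_condition=0,
        )
        counts, meta, _ = synthetic.generate_bulk_experiment(cfg)
        filtered = bulk_de.filter_low_expression(counts, meta["celltype"].to_numpy())
        factors = bulk_de.tmm_factors(filtered)
        logcpm = bulk_de.log_cpm(filtered, factors)
        design = bulk_de.group_design(meta["celltype"].to_numpy())
        weights = bulk_de.mean_variance_weights(logcpm, design)
        fits = bulk_de.fit_and_moderate(logcpm, weights, design)
        contrast = bulk_de.group_contrast(
            design, ["tfh_il21pos", "tfh_il21neg"], ["teff"]
        )
        res = bulk_de.treat_test(fits, contrast, fc_threshold=fc_threshold)
        n_called = int((res["adj.P.Val"] <= fdr).sum())
        called += n_called
        total += len(res)
        per_rep.append(n_called / len(res))
    return {
        "pooled_rate": called / total,
        "max_rep_rate": max(per_rep),
        "n_reps": n_reps,
        "n_tests": total,
    }


def _sc_config(seed: int) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        n_genes=1500,
        n_core_up=80,
        n_core_down=80,
        n_tfr_shared=40,
        n_specific_per_condition=40,
    )


def sc_recovery(seed: int = 2) -> dict[str, float]:
    """Planted 3-cluster single-cell run: clustering ARI and pseudobulk DE recovery."""
    cfg = _sc_config(seed)
    cells, meta, truth = synthetic.generate_singlecell_experiment(cfg)
    filtered, _ = sc_pipeline.qc_filter_cells(cells)
    norm = sc_pipeline.lognormalize_cells(filtered)
    hvgs = sc_pipeline.select_hvgs(norm, n=500)
    emb = sc_pipeline.pca_cells(norm, hvgs, n_components=20)
    graph = sc_pipeline.knn_jaccard_graph(emb, k=9)
    labels = sc_pipeline.louvain_communities(graph, seed=seed)
    ari = adjusted_rand_score(truth.cell_clusters.loc[labels.index], labels)

    pb_meta = meta.loc[filtered.sample_ids].assign(
        cluster=truth.cell_clusters.loc[filtered.sample_ids]
    )
    pb, pbm = sc_pipeline.pseudobulk(filtered, pb_meta, by=["cluster", "donor"])
    # exactness: summed group totals equal the member-cell totals, integer for integer
    keys = pb_meta[["cluster", "donor"]].astype(str).agg("|".join, axis=1)
    member = keys.isin(pbm.index)
    sums_exact = bool(
        (
            pb.as_genes_by_samples().sum(axis=1).to_numpy()
            == filtered.values.loc[member.to_numpy()].sum(axis=0).to_numpy()
        ).all()
    )
    res = sc_pipeline.pseudobulk_de(pb, pbm, "cluster", "0", "1", donor_col="donor")
    d = bulk_de.decide_directions(res)
    m0 = set(truth.genes_in(truth.cluster_programs[0]))
    m1 = set(truth.genes_in(truth.cluster_programs[1]))
    up_called = set(d.index[d == 1])
    down_called = set(d.index[d == -1])
    tp = len(up_called & m0) + len(down_called & m1)
    recall = tp / (len(m0) + len(m1))
    precision = tp / max(len(up_called) + len(down_called), 1)
    return {
        "ari": float(ari),
        "pseudobulk_sums_exact": sums_exact,
        "de_recall": recall,
        "de_precision": precision,
    }


def projection_dominance(
    seeds, holdout_offset: int = 900_000
) -> dict[str, float]:
    """Derive on a training simulation, score held-out replicates, and count
    how often the matching condition's context signature scores highest."""
    per_seed = []
    for seed in seeds:
        cfg = SimulationConfig(seed=seed)
        counts, meta, _ = synthetic.generate_bulk_experiment(cfg)
        sigs, _ = workflow.derive_from_counts(counts, meta)
        held, hmeta, _ = synthetic.generate_bulk_experiment(
            cfg, counts_seed=holdout_offset + seed
        )
        tfh = hmeta["celltype"].str.startswith("tfh")
        sub = CountMatrix(held.as_genes_by_samples().loc[:, tfh.to_numpy()])
        factors = bulk_de.tmm_factors(sub)
        logcpm = bulk_de.log_cpm(sub, factors)
        ctx = {c: sigs[f"{c}_tfh_specific"] for c in cfg.conditions}
        scores = rank_scoring.score_matrix(logcpm, ctx, use="up_only")
        means = rank_scoring.summarize_by_cluster(
            scores, hmeta.loc[scores.index, "condition"]
        )
        diag = sum(means.loc[c].idxmax() == c for c in cfg.conditions)
        per_seed.append(diag / len(cfg.conditions))
    return {
        "dominance_fraction": float(np.mean(per_seed)),
        "min_seed_fraction": float(np.min(per_seed)),
        "n_seeds": len(per_seed),
    }


def region_separation(seed: int = 5, n_perm: int = 999) -> dict[str, float]:
    """Core-up score contrast between planted GC-like regions and background."""
    from .projection import score_regions

    cfg = SimulationConfig(
        seed=seed,
        n_genes=800,
        n_core_up=60,
        n_core_down=60,
        n_tfr_shared=30,
        n_specific_per_condition=20,
        grid_size=30,
        n_regions=3,
        region_radius=4.0,
    )
    ds, truth = synthetic.generate_spatial_experiment(cfg)
    core = GeneSignature("core", frozenset(truth.core_up))
    scores, _ = score_regions(ds, {"core": core})
    in_region = (scores["region"] != "background").to_numpy()
    vals = scores["core"].to_numpy()
    obs = vals[in_region].mean() - vals[~in_region].mean()
    rng = np.random.default_rng(seed)
    n_in = int(in_region.sum())
    hits = 0
    for _ in range(n_perm):
        idx = rng.permutation(len(vals))
        if vals[idx[:n_in]].mean() - vals[idx[n_in:]].mean() >= obs:
            hits += 1
    return {
        "region_minus_background": float(obs),
        "perm_p": (1 + hits) / (1 + n_perm),
    }
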