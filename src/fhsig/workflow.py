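"""End-to-end derivation workflow over a multi-condition sorted-population
bulk experiment.

From a gene x sample count matrix with condition / celltype / replicate
metadata this module runs the full engine — library-size and low-expression
filtering, TMM, log-CPM, precision weights, moderated fits and
fold-change-thresholded tests — for every contrast family the signature
rules need:

* T_FH vs T_eff within each condition, and combined across conditions;
* T_FR vs T_FH and T_FR vs T_eff within each condition;
* one-vs-rest across conditions, separately within T_FH and within T_eff.

and then applies the consensus rules to produce the core, regulatory and
pathogen-specific signatures.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import pandas as pd

from . import bulk_de, signatures
from .io import CountMatrix
from .signatures import GeneSignature

TFH = ("tfh_il21pos", "tfh_il21neg")

__all__ = ["BulkDEOutputs", "run_bulk_de", "derive_signatures", "derive_from_counts"]


@dataclasses.dataclass
class BulkDEOutputs:
    """Directional calls for every contrast family plus the shared log-CPM."""

    logcpm: pd.DataFrame
    tfh_vs_teff: dict[str, pd.Series]  # condition -> calls
    tfh_vs_teff_combined: pd.Series
    tfr_vs_tfh: dict[str, pd.Series]
    tfr_vs_teff: dict[str, pd.Series]
    one_vs_rest_tfh: dict[str, pd.Series]
    one_vs_rest_teff: dict[str, pd.Series]
    results: dict[str, pd.DataFrame]  # full DE tables keyed by contrast name


def _de_calls(
    counts: pd.DataFrame,
    labels: pd.Series,
    contrasts: Mapping[str, tuple[Sequence[str], Sequence[str]]],
    fc_threshold: float,
    fdr: float,
) -> tuple[dict[str, pd.Series], dict[str, pd.DataFrame]]:
    """Fit one group-means model on a sample subset and test named contrasts."""
    cm = CountMatrix(counts, "genes_by_samples")
    factors = bulk_de.tmm_factors(cm)
    logcpm = bulk_de.log_cpm(cm, factors)
    design = bulk_de.group_design(labels.to_numpy())
    weights = bulk_de.mean_variance_weights(logcpm, design)
    fits = bulk_de.fit_and_moderate(logcpm, weights, design)
    calls, tables = {}, {}
    for name, (num, den) in contrasts.items():
        c = bulk_de.group_contrast(design, list(num), list(den))
        res = bulk_de.treat_test(fits, c, fc_threshold=fc_threshold)
        calls[name] = bulk_de.decide_directions(res, fdr=fdr)
        tables[name] = res
    return calls, tables


def run_bulk_de(
    counts: CountMatrix,
    meta: pd.DataFrame,
    fc_threshold: float = 1.1,
    fdr: float = 0.05,
    min_library_size: float = 1e6,
    min_count: float = 10,
    min_total: float = 15,
    pool_il21_subsets: bool = True,
) -> BulkDEOutputs:
    """Run every contrast family the signature rules consume."""
    counts = bulk_de.filter_samples_by_library_size(counts, min_library_size)
    meta = meta.loc[counts.sample_ids]
    group = meta["condition"].astype(str) + "." + meta["celltype"].astype(str)
    counts = bulk_de.filter_low_expression(
        counts, group.to_numpy(), min_count=min_count, min_total=min_total
    )
    gxs = counts.as_genes_by_samples()
    conditions = list(dict.fromkeys(meta["condition"]))

    tfh_levels = list(TFH) if pool_il21_subsets else ["tfh_il21pos"]

    tfh_vs_teff: dict[str, pd.Series] = {}
    tfr_vs_tfh: dict[str, pd.Series] = {}
    tfr_vs_teff: dict[str, pd.Series] = {}
    results: dict[str, pd.DataFrame] = {}

    for cond in conditions:
        use = (meta["condition"] == cond).to_numpy()
        labels = meta.loc[use, "celltype"].astype(str)
        sub = gxs.loc[:, use]
        calls, tables = _de_calls(
            sub,
            labels,
            {
                "tfh_vs_teff": (tfh_levels, ["teff"]),
                "tfr_vs_tfh": (["tfr"], tfh_levels),
                "tfr_vs_teff": (["tfr"], ["teff"]),
            },
            fc_threshold,
            fdr,
        )
        tfh_vs_teff[cond] = calls["tfh_vs_teff"]
        tfr_vs_tfh[cond] = calls["tfr_vs_tfh"]
        tfr_vs_teff[cond] = calls["tfr_vs_teff"]
        for k, t in tables.items():
            results[f"{cond}:{k}"] = t

    # combined T_FH-vs-T_eff: one model over condition x celltype groups,
    # contrast averaging the celltype effect over conditions
    combo_labels = group
    num = [f"{c}.{ct}" for c in conditions for ct in tfh_levels]
    den = [f"{c}.teff" for c in conditions]
    calls, tables = _de_calls(
        gxs, combo_labels, {"combined": (num, den)}, fc_threshold, fdr
    )
    combined = calls["combined"]
    results["combined:tfh_vs_teff"] = tables["combined"]

    def one_vs_rest(celltypes: Sequence[str], tag: str) -> dict[str, pd.Series]:
        use = meta["celltype"].isin(celltypes).to_numpy()
        labels = meta.loc[use, "condition"].astype(str)
        sub = gxs.loc[:, use]
        contrasts = {
            cond: ([cond], [c for c in conditions if c != cond]) for cond in conditions
        }
        calls, tables = _de_calls(sub, labels, contrasts, fc_threshold, fdr)
        for cond, t in tables.items():
            results[f"{cond}:one_vs_rest_{tag}"] = t
        return calls

    ovr_tfh = one_vs_rest(list(TFH), "tfh")
    ovr_teff = one_vs_rest(["teff"], "teff")

    factors = bulk_de.tmm_factors(counts)
    logcpm = bulk_de.log_cpm(counts, factors)
    return BulkDEOutputs(
        logcpm=logcpm,
        tfh_vs_teff=tfh_vs_teff,
        tfh_vs_teff_combined=combined,
        tfr_vs_tfh=tfr_vs_tfh,
        tfr_vs_teff=tfr_vs_teff,
        one_vs_rest_tfh=ovr_tfh,
        one_vs_rest_teff=ovr_teff,
        results=results,
    )


def derive_signatures(
    outputs: BulkDEOutputs, min_conditions: int = 3
) -> dict[str, GeneSignature]:
    """Apply the consensus rules; returns core, tfr and per-condition signatures."""
    sigs: dict[str, GeneSignature] = {}
    sigs["core"] = signatures.derive_core_signature(
        outputs.tfh_vs_teff, outputs.tfh_vs_teff_combined, min_conditions
    )
    sigs["tfr"] = signatures.derive_tfr_signature(
        outputs.tfr_vs_tfh, outputs.tfr_vs_teff, min_conditions
    )
    context = signatures.derive_context_signatures(
        outputs.one_vs_rest_tfh, outputs.one_vs_rest_teff
    )
    for cond, parts in context.items():
        sigs[f"{cond}_tfh_specific"] = parts["tfh_specific"]
    return sigs


def derive_from_counts(
    counts: CountMatrix,
    meta: pd.DataFrame,
    min_conditions: int = 3,
    **engine_kwargs,
) -> tuple[dict[str, GeneSignature], BulkDEOutputs]:
    """Convenience wrapper: engine + rules in one call."""
    outputs = run_bulk_de(counts, meta, **engine_kwargs)
    return derive_signatures(outputs, min_conditions=min_conditions), outputs
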