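"""Project derived signatures onto external-style datasets.

Pseudobulk-then-score workflows for single-cell data, per-region scoring of
spatial data, rank-score-based selection of follicular-helper-like cells on
restricted panels, and per-group dominance summaries (which pathogen
signature scores highest where).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import bulk_de, rank_scoring, sc_pipeline
from .io import CountMatrix, SpatialDataset
from .signatures import GeneSignature

logger = logging.getLogger(__name__)

__all__ = [
    "ProjectionResult",
    "project_signatures",
    "select_tfh_like",
    "score_regions",
    "dominance_summary",
]


@dataclasses.dataclass
class ProjectionResult:
    """Scores per pseudosample plus grouping metadata and per-group means."""

    scores: pd.DataFrame  # pseudosamples x signatures
    group_meta: pd.DataFrame
    group_means: pd.DataFrame  # groups x signatures
    signatures: list[str]


def project_signatures(
    counts: CountMatrix,
    metadata: pd.DataFrame,
    signatures: Mapping[str, GeneSignature],
    group_by: Sequence[str] = ("condition",),
    min_cells: int = 10,
    use: str = "up_only",
    min_count: float = 10,
    min_total: float = 15,
) -> ProjectionResult:
    """Pseudobulk cells on the grouping factors, normalize, and rank-score.

    The pipeline is pseudobulk -> low-expression filter -> TMM -> log-CPM ->
    rank score on the (by default upregulated) signature genes, then mean
    score per level of the first grouping factor.
    """
    pb, pb_meta = sc_pipeline.pseudobulk(
        counts, metadata, by=list(group_by), min_cells=min_cells
    )
    filtered = bulk_de.filter_low_expression(
        pb, pb_meta[group_by[0]].to_numpy(), min_count=min_count, min_total=min_total
    )
    if filtered.shape[1] >= 2:
        factors = bulk_de.tmm_factors(filtered)
    else:  # a single pseudosample cannot be normalized against anything
        factors = pd.Series(1.0, index=filtered.sample_ids)
    logcpm = bulk_de.log_cpm(filtered, factors)
    scores = rank_scoring.score_matrix(logcpm, signatures, use=use)
    labels = pd.Series(pb_meta[group_by[0]].to_numpy(), index=scores.index)
    group_means = rank_scoring.summarize_by_cluster(scores, labels)
    return ProjectionResult(
        scores=scores,
        group_meta=pb_meta,
        group_means=group_means,
        signatures=list(signatures),
    )


def select_tfh_like(
    cells: CountMatrix,
    core_signature: GeneSignature,
    allowed_annotations: Sequence[str] | None = None,
    annotations: pd.Series | None = None,
) -> pd.Index:
    """Select follicular-helper-like cells on a restricted panel.

    Optionally restrict to annotated cell types, then keep cells whose
    bidirectional core score (up and down sets) is strictly positive.
    """
    if not core_signature.up or not core_signature.down:
        raise ValueError("core signature must carry both up and down sets")
    cxg = cells.values if cells.orientation == "cells_by_genes" else cells.values.T
    ids = cxg.index
    if allowed_annotations is not None:
        if len(allowed_annotations) == 0:
            raise ValueError("allowed annotation set must not be empty")
        if annotations is None:
            raise ValueError("annotations required when filtering on them")
        keep = annotations.reindex(ids).isin(list(allowed_annotations))
        ids = ids[keep.to_numpy()]
    if len(ids) == 0:
        return pd.Index([])
    expr = np.log2(cxg.loc[ids].T + 1.0)  # genes x cells
    scores = rank_scoring.score_matrix(
        expr, {"core": core_signature}, use="bidirectional"
    )["core"]
    return ids[(scores > 0).to_numpy()]


def _coverage_check(
    universe: pd.Index, signatures: Mapping[str, GeneSignature], min_coverage: float
) -> None:
    for name, sig in signatures.items():
        genes = sig.up | sig.down
        cov = len(set(genes) & set(universe)) / len(genes) if genes else 0.0
        if cov < min_coverage:
            raise ValueError(
                f"signature {name!r}: only {cov:.0%} of its genes are on the panel "
                f"(minimum {min_coverage:.0%})"
            )
        if cov < 1.0:
            logger.warning(
                "signature %s: %.0f%% of genes present on the panel", name, cov * 100
            )


def score_regions(
    spatial: SpatialDataset,
    signatures: Mapping[str, GeneSignature],
    use: str = "up_only",
    min_coverage: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every spot; summarize per region with unlabeled spots as background.

    Returns (per-spot scores with a ``region`` column, per-region mean/median
    table).  Errors when a signature covers less than ``min_coverage`` of its
    genes on the panel.
    """
    cxg = (
        spatial.counts.values
        if spatial.counts.orientation == "cells_by_genes"
        else spatial.counts.values.T
    )
    _coverage_check(cxg.columns, signatures, min_coverage)
    expr = np.log2(cxg.T + 1.0)  # genes x spots
    scores = rank_scoring.score_matrix(expr, signatures, use=use)
    region = (
        spatial.region_labels.reindex(scores.index)
        if spatial.region_labels is not None
        else pd.Series(np.nan, index=scores.index)
    )
    scores = scores.copy()
    scores["region"] = region.fillna("background")
    summaries = []
    for reg, grp in scores.groupby("region"):
        vals = grp.drop(columns="region")
        for sig in vals.columns:
            summaries.append(
                {
                    "region": reg,
                    "signature": sig,
                    "n_spots": len(vals),
                    "mean": vals[sig].mean(),
                    "median": vals[sig].median(),
                }
            )
    return scores, pd.DataFrame(summaries)


def dominance_summary(result: ProjectionResult) -> pd.DataFrame:
    """Per group: the top-scoring signature, its margin, and the full ranking."""
    means = result.group_means
    if means.shape[1] < 2:
        raise ValueError("dominance needs at least two signatures")
    rows = []
    for group, row in means.iterrows():
        ordered = row.sort_values(ascending=False)
        top, runner = ordered.index[0], ordered.index[1]
        tie = np.isclose(ordered.iloc[0], ordered.iloc[1])
        rows.append(
            {
                "group": group,
                "dominant": f"{top}|{runner}" if tie else top,
                "tie": bool(tie),
                "margin": float(ordered.iloc[0] - ordered.iloc[1]),
                "ranking": ",".join(ordered.index),
            }
        )
    return pd.DataFrame(rows).set_index("group")
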