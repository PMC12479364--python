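"""Rank-based single-sample signature scoring.

Within each sample, genes are ranked by expression (ascending, ties
averaged).  The score of an up-regulated set is the mean rank of its genes,
min-max normalized by the analytic extremes

    min mean rank = (n_up + 1) / 2,    max mean rank = (2N - n_up + 1) / 2

and centered by -0.5, giving a score in [-0.5, +0.5] that is invariant under
any strictly monotone transform of the expression values.  A down set is
scored the same way on reversed ranks; the total bidirectional score is the
sum (range [-1, +1]).  Signature genes absent from a dataset's gene universe
are dropped with a warning and the bounds are recomputed on the present
subset, which keeps the score meaningful on restricted panels.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .signatures import GeneSignature

logger = logging.getLogger(__name__)

__all__ = [
    "rank_genes",
    "signature_score",
    "score_matrix",
    "summarize_by_cluster",
    "normalize_to_baseline",
]


def rank_genes(expression_vector: pd.Series | np.ndarray) -> np.ndarray:
    """Ascending ranks with average ties; ranks sum to N(N+1)/2."""
    x = np.asarray(
        expression_vector.to_numpy()
        if isinstance(expression_vector, pd.Series)
        else expression_vector,
        dtype=float,
    )
    if x.size == 0:
        raise ValueError("cannot rank an empty expression vector")
    if not np.isfinite(x).all():
        raise ValueError("expression values must be finite")
    return stats.rankdata(x, method="average")


def _directional_score(ranks: np.ndarray, idx: np.ndarray) -> float:
    """Normalized centered mean rank of the genes at positions ``idx``."""
    n = len(ranks)
    n_set = len(idx)
    mean_rank = ranks[idx].mean()
    lo = (n_set + 1) / 2.0
    hi = (2 * n - n_set + 1) / 2.0
    if hi == lo:  # the set covers the whole universe
        return 0.0
    return float((mean_rank - lo) / (hi - lo) - 0.5)


def signature_score(
    expression_vector: pd.Series,
    up_set: Sequence[str] | frozenset,
    down_set: Sequence[str] | frozenset | None = None,
    signature_name: str = "signature",
    warn_missing: bool = True,
) -> dict[str, float]:
    """Score one sample against an up (and optionally down) gene set.

    Returns ``up_score``, ``down_score`` (NaN without a down set),
    ``total_score`` and the counts of signature genes present.
    """
    universe = expression_vector.index
    pos = {g: i for i, g in enumerate(universe)}
    up_present = [g for g in sorted(set(up_set)) if g in pos]
    if set(up_set) and not up_present:
        raise ValueError(
            f"no up-set genes of {signature_name!r} present in the expression data"
        )
    dropped = len(set(up_set)) - len(up_present)
    if dropped and warn_missing:
        logger.warning(
            "%s: %d up-set genes absent from the dataset; bounds recomputed",
            signature_name,
            dropped,
        )
    ranks = rank_genes(expression_vector)
    up_idx = np.array([pos[g] for g in up_present], dtype=int)
    up_score = _directional_score(ranks, up_idx)

    down_score = float("nan")
    total = up_score
    if down_set is not None and len(set(down_set)):
        down_present = [g for g in sorted(set(down_set)) if g in pos]
        if not down_present:
            raise ValueError(
                f"no down-set genes of {signature_name!r} present in the expression data"
            )
        if (len(set(down_set)) - len(down_present)) and warn_missing:
            logger.warning(
                "%s: %d down-set genes absent from the dataset; bounds recomputed",
                signature_name,
                len(set(down_set)) - len(down_present),
            )
        rev = len(ranks) + 1 - ranks
        down_idx = np.array([pos[g] for g in down_present], dtype=int)
        down_score = _directional_score(rev, down_idx)
        total = up_score + down_score

    return {
        "up_score": up_score,
        "down_score": down_score,
        "total_score": total,
        "n_up_present": len(up_present),
        "n_down_present": (
            len(down_present) if down_set is not None and len(set(down_set)) else 0
        ),
    }


def score_matrix(
    expression_matrix: pd.DataFrame,
    signatures: Mapping[str, GeneSignature],
    use: str = "up_only",
) -> pd.DataFrame:
    """Score every sample (column) against every signature.

    ``use='up_only'`` scores the up sets alone (the projection default);
    ``use='bidirectional'`` adds the reversed-rank down-set score.
    """
    if use not in ("up_only", "bidirectional"):
        raise ValueError(f"unknown scoring mode: {use!r}")
    out = pd.DataFrame(index=expression_matrix.columns, dtype=float)
    universe = set(expression_matrix.index)
    for name, sig in signatures.items():
        down = sig.down if (use == "bidirectional" and sig.down) else None
        n_missing = len(set(sig.up) - universe)
        if down is not None:
            n_missing += len(set(down) - universe)
        if n_missing:
            logger.warning(
                "%s: %d signature genes absent from the dataset; bounds recomputed",
                name,
                n_missing,
            )
        vals = [
            signature_score(
                expression_matrix[c], sig.up, down, signature_name=name,
                warn_missing=False,
            )["total_score"]
            for c in expression_matrix.columns
        ]
        out[name] = vals
    return out


def summarize_by_cluster(
    scores: pd.DataFrame, labels: pd.Series, zscore: bool = False
) -> pd.DataFrame:
    """Mean score per cluster per signature; optional per-signature z-scaling."""
    labels = labels.reindex(scores.index)
    if labels.isna().any():
        missing = scores.index[labels.isna()].tolist()
        raise ValueError(f"labels missing for samples: {missing[:10]}")
    means = scores.groupby(labels).mean()
    if zscore:
        sd = means.std(axis=0, ddof=1)
        means = (means - means.mean(axis=0)) / sd.replace(0, np.nan)
        means = means.fillna(0.0)
    return means


def normalize_to_baseline(
    score_series: pd.Series,
    baseline_key,
    mode: str = "difference",
) -> pd.Series:
    """Normalize a score series to a baseline entry (e.g. the first time point).

    ``difference``: value - baseline; ``ratio``: value / baseline (errors on a
    non-positive baseline).
    """
    if isinstance(baseline_key, (list, tuple, pd.Index)):
        missing = [k for k in baseline_key if k not in score_series.index]
        if missing:
            raise ValueError(f"baseline entries not found: {missing}")
        baseline = score_series.loc[list(baseline_key)].mean()
    else:
        if baseline_key not in score_series.index:
            raise ValueError(f"baseline entry not found: {baseline_key!r}")
        baseline = score_series.loc[baseline_key]
    if mode == "difference":
        return score_series - baseline
    if mode == "ratio":
        if baseline <= 0:
            raise ValueError("ratio normalization needs a positive baseline")
        return score_series / baseline
    raise ValueError(f"unknown mode: {mode!r}")
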