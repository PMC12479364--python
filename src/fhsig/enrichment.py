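"""Preranked gene-set enrichment and gene-set overlap-graph clustering.

The enrichment score is the classic weighted Kolmogorov-Smirnov-like running
sum: walking down a ranked gene list, set members increment the sum by
|stat|^p / sum_set |stat|^p and non-members decrement it by 1/(N - n_set);
the ES is the extremum of larger magnitude.  Significance comes from a
gene-set permutation null (random same-size sets), enumerated exhaustively
when the number of possible sets is small; NES divides the ES by the mean
|null ES| of matching sign.
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .bulk_de import adjust_bh
from .io import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "enrichment_score",
    "permutation_test",
    "gsea_batch",
    "overlap_coefficient",
    "gene_set_components",
]

EXHAUSTIVE_LIMIT = 10_000


def _as_ranked(ranked: pd.Series) -> pd.Series:
    if ranked.index.has_duplicates:
        raise ValueError("ranked list contains duplicate genes")
    if not np.isfinite(ranked.to_numpy(dtype=float)).all():
        raise ValueError("ranking statistic must be finite")
    return ranked.sort_values(ascending=False, kind="mergesort")


def _walk_es(
    stats_desc: np.ndarray, hit_mask: np.ndarray, weight_p: float
) -> tuple[float, np.ndarray]:
    n = len(stats_desc)
    n_set = int(hit_mask.sum())
    if n_set == 0 or n_set >= n:
        raise ValueError("gene set must hit >= 1 and < all ranked genes")
    w = np.abs(stats_desc) ** weight_p
    hit_total = w[hit_mask].sum()
    steps = np.where(
        hit_mask,
        (w / hit_total) if hit_total > 0 else (1.0 / n_set),
        -1.0 / (n - n_set),
    )
    if hit_total == 0:
        # all hit statistics are zero: fall back to unweighted increments
        steps = np.where(hit_mask, 1.0 / n_set, -1.0 / (n - n_set))
    running = np.cumsum(steps)
    hi = running.max()
    lo = running.min()
    # on an exact magnitude tie the positive extremum is chosen
    es = hi if hi >= -lo else lo
    return float(es), running


def enrichment_score(
    ranked: pd.Series, gene_set: Iterable[str], weight_p: float = 1.0
) -> tuple[float, np.ndarray]:
    """ES and running sum for one gene set over a descending ranked list."""
    ranked = _as_ranked(ranked)
    members = set(gene_set)
    hit = np.fromiter((g in members for g in ranked.index), dtype=bool, count=len(ranked))
    return _walk_es(ranked.to_numpy(dtype=float), hit, weight_p)


def permutation_test(
    ranked: pd.Series,
    gene_set: Iterable[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
) -> dict:
    """Gene-set permutation p-value and NES for one set.

    Null ES values come from random same-size gene sets.  When the number of
    possible sets is at most 10,000 the null is enumerated exhaustively and
    p = #{null ES at least as extreme, same sign}/#total; otherwise p uses
    the standard (1 + hits)/(1 + n_perm) Monte-Carlo estimator.  NES = ES
    divided by the mean |null ES| of matching sign.
    """
    ranked = _as_ranked(ranked)
    stats_desc = ranked.to_numpy(dtype=float)
    members = set(gene_set) & set(ranked.index)
    n = len(ranked)
    n_set = len(members)
    if n_set == 0 or n_set >= n:
        raise ValueError("gene set must hit >= 1 and < all ranked genes")
    hit = np.fromiter((g in members for g in ranked.index), dtype=bool, count=n)
    es, _ = _walk_es(stats_desc, hit, weight_p)

    exhaustive = math.comb(n, n_set) <= EXHAUSTIVE_LIMIT
    null_es = []
    if exhaustive:
        for combo in itertools.combinations(range(n), n_set):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            null_es.append(_walk_es(stats_desc, mask, weight_p)[0])
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=n_set, replace=False)] = True
            null_es.append(_walk_es(stats_desc, mask, weight_p)[0])
    null_es = np.asarray(null_es)
    if np.allclose(null_es, null_es[0]):
        logger.warning("degenerate permutation null: all null ES equal")

    sign = 1.0 if es >= 0 else -1.0
    same_sign = null_es * sign >= 0
    extreme = same_sign & (np.abs(null_es) >= abs(es))
    if exhaustive:
        p = extreme.sum() / len(null_es)
    else:
        p = (1 + extreme.sum()) / (1 + len(null_es))
    denom = np.abs(null_es[same_sign]).mean() if same_sign.any() else np.nan
    nes = es / denom if denom and denom > 0 else np.nan
    return {
        "es": es,
        "nes": float(nes),
        "pval": float(p),
        "n_null": len(null_es),
        "exhaustive": exhaustive,
    }


def _leading_edge(ranked: pd.Series, members: set[str], es: float, running: np.ndarray) -> list[str]:
    genes = ranked.index.to_numpy()
    if es >= 0:
        cut = int(np.argmax(running))
        zone = genes[: cut + 1]
    else:
        cut = int(np.argmin(running))
        zone = genes[cut:]
    return [g for g in zone if g in members]


def gsea_batch(
    ranked: pd.Series,
    collection: GeneSetCollection,
    min_size: int = 5,
    max_size: int = 500,
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
) -> pd.DataFrame:
    """Run the permutation GSEA over a collection; BH-adjust across sets."""
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    ranked = _as_ranked(ranked)
    universe = set(ranked.index)
    rows = []
    for i, s in enumerate(collection):
        members = set(s.members) & universe
        if not (min_size <= len(members) <= max_size):
            logger.info(
                "skipping %s: %d genes in universe outside [%d, %d]",
                s.name,
                len(members),
                min_size,
                max_size,
            )
            continue
        res = permutation_test(
            ranked, members, n_perm=n_perm, seed=seed + i, weight_p=weight_p
        )
        es, running = enrichment_score(ranked, members, weight_p)
        rows.append(
            {
                "set": s.name,
                "size": len(members),
                "ES": res["es"],
                "NES": res["nes"],
                "pval": res["pval"],
                "leading_edge": ",".join(_leading_edge(ranked, members, es, running)),
            }
        )
    out = pd.DataFrame(rows, columns=["set", "size", "ES", "NES", "pval", "leading_edge"])
    if len(out):
        out["padj"] = adjust_bh(out["pval"].to_numpy())
        out = out[["set", "size", "ES", "NES", "pval", "padj", "leading_edge"]]
    return out


def overlap_coefficient(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """|A intersect B| / min(|A|, |B|)."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("overlap coefficient is undefined for empty sets")
    return len(a & b) / min(len(a), len(b))


def gene_set_components(
    collection: GeneSetCollection, threshold: float
) -> tuple[nx.Graph, pd.DataFrame]:
    """Overlap-coefficient graph and its connected components at a threshold.

    Edges join sets whose overlap coefficient reaches the threshold; the
    component table summarizes each component by its member sets and the
    union of their genes.
    """
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    graph = nx.Graph()
    names = collection.names
    graph.add_nodes_from(names)
    for a, b in itertools.combinations(names, 2):
        oc = overlap_coefficient(collection.members(a), collection.members(b))
        if oc >= threshold:
            graph.add_edge(a, b, weight=oc)
    rows = []
    for i, comp in enumerate(sorted(nx.connected_components(graph), key=sorted), 1):
        union = set().union(*(collection.members(n) for n in comp))
        rows.append(
            {
                "component": i,
                "sets": ",".join(sorted(comp)),
                "n_sets": len(comp),
                "n_genes": len(union),
            }
        )
    return graph, pd.DataFrame(rows)
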