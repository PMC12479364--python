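"""Single-cell stage: QC, normalization, clustering, pseudobulking and
pseudobulk differential expression.

Cells are QC-filtered on mitochondrial fraction and count-depth quantiles,
log-normalized with median-library size factors, reduced by PCA on the top
highly variable genes, and clustered with Louvain communities on a
Jaccard-weighted k-nearest-neighbour graph.  Clusters are pseudobulked per
(cluster, sample) group and tested with the bulk DE engine, with donor as a
fixed-effect covariate.  Antibody-tag (protein) counts get a centered
log-ratio transform.
"""

from __future__ import annotations

import random
from typing import Sequence

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from . import bulk_de
from .io import CountMatrix

__all__ = [
    "qc_filter_cells",
    "lognormalize_cells",
    "select_hvgs",
    "pca_cells",
    "knn_jaccard_graph",
    "louvain_communities",
    "pseudobulk",
    "pseudobulk_de",
    "clr_normalize_protein",
]

MITO_PREFIXES = ("mt-", "MT-")


def mito_fraction(cells: CountMatrix, prefixes: Sequence[str] = MITO_PREFIXES) -> pd.Series:
    cxg = cells.values if cells.orientation == "cells_by_genes" else cells.values.T
    mito_cols = [g for g in cxg.columns if str(g).startswith(tuple(prefixes))]
    total = cxg.sum(axis=1)
    if not mito_cols:
        return pd.Series(0.0, index=cxg.index)
    return cxg[mito_cols].sum(axis=1) / total.replace(0, np.nan)


def qc_filter_cells(
    cells: CountMatrix,
    mito_max: float = 0.20,
    count_quantile: float = 0.10,
    mito_prefixes: Sequence[str] = MITO_PREFIXES,
    require_mito_genes: bool = True,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Remove damaged / empty cells.

    Cells with mitochondrial fraction >= ``mito_max`` (inclusive) are
    removed, as are cells whose total counts or detected genes fall strictly
    below the ``count_quantile``-th quantile (linear-interpolation
    convention).  Returns the filtered matrix and a per-cell QC table with
    the removal reason.
    """
    cxg = cells.values if cells.orientation == "cells_by_genes" else cells.values.T
    mito_cols = [g for g in cxg.columns if str(g).startswith(tuple(mito_prefixes))]
    if require_mito_genes and mito_max < 1 and not mito_cols:
        raise ValueError(
            f"no mitochondrial genes found with prefixes {tuple(mito_prefixes)}"
        )
    total = cxg.sum(axis=1).astype(float)
    detected = (cxg > 0).sum(axis=1).astype(float)
    mfrac = (
        cxg[mito_cols].sum(axis=1) / total.replace(0, np.nan)
        if mito_cols
        else pd.Series(0.0, index=cxg.index)
    ).fillna(0.0)

    reasons = pd.Series("", index=cxg.index, dtype=object)
    reasons[mfrac >= mito_max] += "high_mito;"
    if count_quantile > 0:
        total_cut = np.quantile(total, count_quantile)  # type-7 linear interpolation
        detected_cut = np.quantile(detected, count_quantile)
        reasons[total < total_cut] += "low_counts;"
        reasons[detected < detected_cut] += "low_genes;"

    qc = pd.DataFrame(
        {
            "total_counts": total,
            "detected_genes": detected,
            "mito_fraction": mfrac,
            "removed_reason": reasons.str.rstrip(";"),
        }
    )
    keep = reasons == ""
    filtered = CountMatrix(cxg.loc[keep], "cells_by_genes")
    return filtered, qc


def lognormalize_cells(cells: CountMatrix) -> pd.DataFrame:
    """log2(count / size_factor + 1), size factor = cell total / median total."""
    cxg = cells.values if cells.orientation == "cells_by_genes" else cells.values.T
    totals = cxg.sum(axis=1).astype(float)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"zero-total cells must be removed before normalization: {bad[:5]}")
    sf = totals / np.median(totals)
    return np.log2(cxg.div(sf, axis=0) + 1.0)


def select_hvgs(normalized: pd.DataFrame, n: int = 2000) -> list[str]:
    """Top-n genes by variance of the normalized values; ties broken by gene id."""
    var = normalized.var(axis=0, ddof=1)
    order = sorted(var.index, key=lambda g: (-var[g], str(g)))
    return order[: min(n, len(order))]


def pca_cells(
    normalized: pd.DataFrame,
    hvgs: Sequence[str] | None = None,
    n_components: int = 30,
) -> pd.DataFrame:
    """Gene-centered PCA of the HVG submatrix with a fixed sign convention."""
    sub = normalized[list(hvgs)] if hvgs is not None else normalized
    n_components = min(n_components, min(sub.shape) - 1)
    if n_components < 1:
        raise ValueError("matrix too small for PCA")
    X = sub.to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    if not np.isfinite(X).all():
        raise ValueError("normalized matrix contains non-finite values")
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    for k in range(n_components):
        i = np.argmax(np.abs(vt[k]))
        if vt[k, i] < 0:
            vt[k, :] *= -1
            u[:, k] *= -1
    coords = u[:, :n_components] * s[:n_components]
    out = pd.DataFrame(
        coords, index=sub.index, columns=[f"PC{k + 1}" for k in range(n_components)]
    )
    out.attrs["variance_fraction"] = (s**2 / (s**2).sum())[:n_components]
    return out


def knn_jaccard_graph(embedding: pd.DataFrame, k: int = 9) -> nx.Graph:
    """Jaccard-weighted shared-nearest-neighbour graph.

    An edge joins i and j when either lies in the other's k-neighbourhood
    (self excluded); its weight is the Jaccard similarity of the two
    k-neighbour sets.  Zero-weight edges are dropped.
    """
    n = len(embedding)
    if k >= n:
        raise ValueError(f"k = {k} must be smaller than the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding.to_numpy())
    _, idx = nn.kneighbors(embedding.to_numpy())
    ids = embedding.index.to_numpy()
    neigh: list[set[int]] = []
    for i in range(n):
        s = [j for j in idx[i] if j != i][:k]
        neigh.append(set(s))

    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for i in range(n):
        for j in neigh[i]:
            if graph.has_edge(ids[i], ids[j]):
                continue
            inter = len(neigh[i] & neigh[j])
            union = len(neigh[i] | neigh[j])
            if union and inter:
                graph.add_edge(ids[i], ids[j], weight=inter / union)
    return graph


def louvain_communities(
    graph: nx.Graph, resolution: float = 1.0, seed: int = 0
) -> pd.Series:
    """Louvain multi-level modularity clustering; deterministic given the seed.

    Returns 1-based contiguous labels; the achieved modularity is stored in
    the ``modularity`` attribute of the result.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = list(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[a], index[b]) for a, b in graph.edges]
    weights = [graph.edges[a, b].get("weight", 1.0) for a, b in graph.edges]
    g = ig.Graph(n=len(nodes), edges=edges)
    ig.set_random_number_generator(random.Random(seed))
    clustering = g.community_multilevel(weights=weights or None, resolution=resolution)
    ig.set_random_number_generator(random)  # restore the default generator
    labels = np.asarray(clustering.membership) + 1
    out = pd.Series(labels, index=pd.Index(nodes), name="cluster", dtype=int)
    out.attrs["modularity"] = clustering.modularity
    return out


def pseudobulk(
    cells: CountMatrix,
    meta: pd.DataFrame,
    by: Sequence[str] = ("cluster", "sample"),
    min_cells: int = 10,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Sum counts per group of cells; drop groups below the cell cutoff.

    Returns a genes x groups count matrix plus per-group metadata carrying
    the grouping factors and the number of member cells.
    """
    cxg = cells.values if cells.orientation == "cells_by_genes" else cells.values.T
    for col in by:
        if col not in meta.columns:
            raise ValueError(f"grouping factor {col!r} missing from cell metadata")
    meta = meta.loc[cxg.index]
    key = meta[list(by)].astype(str).agg("|".join, axis=1)
    sums = cxg.groupby(key, sort=True).sum()
    counts_per_group = key.value_counts()
    keep = [g for g in sums.index if counts_per_group[g] >= min_cells]
    if not keep:
        raise ValueError(f"no pseudobulk group reaches min_cells = {min_cells}")
    sums = sums.loc[keep]
    group_meta = pd.DataFrame(
        [dict(zip(by, g.split("|"))) for g in sums.index], index=sums.index
    )
    group_meta["n_cells"] = [int(counts_per_group[g]) for g in sums.index]
    return CountMatrix(sums.T, "genes_by_samples"), group_meta


def pseudobulk_de(
    pb_counts: CountMatrix,
    pb_meta: pd.DataFrame,
    group_col: str,
    group_a: str,
    group_b: str,
    donor_col: str | None = None,
    fc_threshold: float = 1.1,
    min_count: float = 10,
    min_total: float = 15,
) -> pd.DataFrame:
    """Bulk-engine DE between two pseudobulk groups (donor as fixed effect).

    Runs low-expression filtering, TMM, precision weights, the moderated
    fit, and the fold-change-thresholded test for group_a vs group_b.
    """
    labels = pb_meta[group_col].astype(str)
    use = labels.isin([group_a, group_b])
    if labels[use].nunique() < 2:
        raise ValueError("both contrast levels must be present after filtering")
    sub = CountMatrix(pb_counts.as_genes_by_samples().loc[:, use.to_numpy()], "genes_by_samples")
    sub_meta = pb_meta.loc[use.to_numpy()]
    sub_labels = sub_meta[group_col].astype(str)

    covar = None
    if donor_col is not None:
        donors = sub_meta[donor_col].astype(str)
        if donors.nunique() > 1:
            # donor must not alias the contrast
            tab = pd.crosstab(donors, sub_labels)
            if (tab > 0).sum(axis=1).max() == 1 and (tab > 0).sum(axis=1).min() == 1:
                raise ValueError("donor is confounded with the contrast groups")
            covar = pd.DataFrame({donor_col: donors.to_numpy()}, index=sub_labels.index)

    filtered = bulk_de.filter_low_expression(
        sub, sub_labels.to_numpy(), min_count=min_count, min_total=min_total
    )
    factors = bulk_de.tmm_factors(filtered)
    logcpm = bulk_de.log_cpm(filtered, factors)
    design = bulk_de.group_design(sub_labels.to_numpy(), covariates=covar)
    weights = bulk_de.mean_variance_weights(logcpm, design)
    fits = bulk_de.fit_and_moderate(logcpm, weights, design)
    contrast = bulk_de.group_contrast(design, [group_a], [group_b])
    return bulk_de.treat_test(fits, contrast, fc_threshold=fc_threshold)


def clr_normalize_protein(protein_counts: pd.DataFrame, pseudo: float = 1.0) -> pd.DataFrame:
    """Centered log-ratio transform of antibody-tag counts, per cell (row).

    v_i = ln(x_i + pseudo) - mean_j ln(x_j + pseudo); rows sum to zero.
    """
    if (protein_counts.to_numpy() < 0).any():
        raise ValueError("protein counts must be non-negative")
    logged = np.log(protein_counts.astype(float) + pseudo)
    return logged.sub(logged.mean(axis=1), axis=0)
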