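"""Bulk differential-expression engine.

Filtering, trimmed-mean-of-M-values normalization, precision-weighted linear
modeling with an empirical-Bayes moderated t statistic, fold-change-thresholded
testing, Benjamini-Hochberg FDR, and {-1, 0, +1} directional calls.

Statistical construction
------------------------
Per gene g a weighted least-squares fit of log-CPM against a design matrix X
yields coefficients beta_g, residual variance s_g^2 on d_g = n - rank(X)
degrees of freedom, and unscaled contrast standard errors u_g.  The residual
variances are shrunk toward a common prior: with prior degrees of freedom d0
and prior variance s0^2 (both estimated by method of moments on log s_g^2),

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and the moderated t uses s~_g and d0 + d_g degrees of freedom.  The
fold-change-thresholded test (null: |true log2FC| <= tau) combines the two
one-sided tail probabilities

    p = P(T >= (|b| - tau)/se) + P(T >= (|b| + tau)/se),   T ~ t_{d0 + d_g}

which reduces to the two-sided moderated-t p-value at tau = 0.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import CountMatrix

__all__ = [
    "GeneFits",
    "sum_technical_replicates",
    "filter_samples_by_library_size",
    "filter_low_expression",
    "tmm_factors",
    "effective_library_sizes",
    "log_cpm",
    "group_design",
    "group_contrast",
    "mean_variance_weights",
    "fit_and_moderate",
    "treat_test",
    "adjust_bh",
    "decide_directions",
    "qc_embeddings",
]

PRIOR_DF_CAP = 1e6  # stands in for an infinite prior (complete shrinkage)


# ---------------------------------------------------------------------------
# count preprocessing


def sum_technical_replicates(
    counts: CountMatrix, replicate_groups: Mapping[str, str]
) -> CountMatrix:
    """Sum columns that are technical replicates (sequencing runs) of one sample."""
    gxs = counts.as_genes_by_samples()
    unassigned = [s for s in gxs.columns if s not in replicate_groups]
    if unassigned:
        raise ValueError(f"samples not assigned to a replicate group: {unassigned[:10]}")
    groups = pd.Series({s: replicate_groups[s] for s in gxs.columns})
    summed = gxs.T.groupby(groups, sort=False).sum().T
    return CountMatrix(summed, "genes_by_samples")


def filter_samples_by_library_size(
    counts: CountMatrix, min_reads: float = 1e6
) -> CountMatrix:
    """Drop samples with library size strictly below ``min_reads``."""
    gxs = counts.as_genes_by_samples()
    totals = gxs.sum(axis=0)
    keep = totals >= min_reads
    if not keep.any():
        raise ValueError(f"all samples have library size < {min_reads:g}")
    return CountMatrix(gxs.loc[:, keep], "genes_by_samples")


def filter_low_expression(
    counts: CountMatrix,
    group_labels: Sequence[str] | pd.Series,
    min_count: float = 10,
    min_total: float = 15,
) -> CountMatrix:
    """Remove genes without worthwhile expression in at least one group.

    A gene is kept iff its CPM reaches ``min_count`` re-expressed at the
    median library size (i.e. CPM >= min_count / median-library-in-millions)
    in at least as many samples as the smallest group holds, and its total
    count reaches ``min_total``.
    """
    gxs = counts.as_genes_by_samples()
    labels = pd.Series(np.asarray(group_labels), index=gxs.columns)
    sizes = labels.value_counts()
    if (sizes == 0).any() or len(sizes) == 0:
        raise ValueError("every group must contain at least one sample")
    k = int(sizes.min())

    lib = gxs.sum(axis=0).to_numpy(dtype=float)
    cpm = gxs.to_numpy(dtype=float) / lib[None, :] * 1e6
    cpm_cutoff = min_count / (np.median(lib) / 1e6)
    enough_samples = (cpm >= cpm_cutoff).sum(axis=1) >= k
    enough_total = gxs.sum(axis=1).to_numpy() >= min_total
    keep = enough_samples & enough_total
    return CountMatrix(gxs.loc[keep], "genes_by_samples")


# ---------------------------------------------------------------------------
# TMM normalization


def _quantile75_over_libsize(col: np.ndarray) -> float:
    return float(np.quantile(col, 0.75)) / float(col.sum())


def tmm_factors(
    counts: CountMatrix | pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors (geometric mean 1).

    The reference sample is the one whose upper-quartile CPM is closest to
    the mean of those.  For each sample, log2 expression ratios M and average
    log2 abundances A are computed over genes positive in both sample and
    reference, doubly trimmed (``trim_m`` on each M tail, ``trim_a`` on each
    A tail, rank-based), and the factor is 2 to the precision-weighted mean
    of the surviving M values, with inverse delta-method variances as
    weights.
    """
    gxs = counts.as_genes_by_samples() if isinstance(counts, CountMatrix) else counts
    if gxs.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    x = gxs.to_numpy(dtype=float)
    lib = x.sum(axis=0)

    f75 = np.array([_quantile75_over_libsize(x[:, j]) for j in range(x.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(x.shape[1])
    for j in range(x.shape[1]):
        factors[j] = _tmm_pair(x[:, j], x[:, ref], lib[j], lib[ref], trim_m, trim_a)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=gxs.columns, name="norm_factor")


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        raise ValueError("sample shares no positive genes with the reference")
    o = obs[pos] / lib_obs
    r = ref[pos] / lib_ref
    m = np.log2(o / r)
    a = (np.log2(o) + np.log2(r)) / 2.0
    # delta-method variance of M
    v = (lib_obs - obs[pos]) / (lib_obs * obs[pos]) + (lib_ref - ref[pos]) / (
        lib_ref * ref[pos]
    )
    if np.max(np.abs(m)) < 1e-6:
        return 1.0  # exact scaling between samples

    n = len(m)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def effective_library_sizes(
    counts: CountMatrix | pd.DataFrame, norm_factors: pd.Series
) -> pd.Series:
    gxs = counts.as_genes_by_samples() if isinstance(counts, CountMatrix) else counts
    return gxs.sum(axis=0) * norm_factors.reindex(gxs.columns)


def log_cpm(
    counts: CountMatrix | pd.DataFrame,
    norm_factors: pd.Series | None = None,
    prior: float = 0.5,
) -> pd.DataFrame:
    """log2 counts per million on effective library sizes.

    logcpm = log2( (y + prior) / (L + 2 prior) * 1e6 ), L = colsum * factor.
    """
    gxs = counts.as_genes_by_samples() if isinstance(counts, CountMatrix) else counts
    if norm_factors is None:
        norm_factors = pd.Series(1.0, index=gxs.columns)
    eff = effective_library_sizes(gxs, norm_factors).to_numpy(dtype=float)
    if np.any(eff <= 0):
        raise ValueError("effective library sizes must be positive")
    y = gxs.to_numpy(dtype=float)
    vals = np.log2((y + prior) / (eff[None, :] + 2 * prior) * 1e6)
    return pd.DataFrame(vals, index=gxs.index, columns=gxs.columns)


# ---------------------------------------------------------------------------
# designs and contrasts


def group_design(
    labels: Sequence[str] | pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Group-means design: one indicator column per group level.

    Optional covariates (e.g. donor) are appended as treatment-coded
    indicators (first level dropped).
    """
    labels = pd.Series(labels) if not isinstance(labels, pd.Series) else labels
    design = pd.get_dummies(labels.astype(str), prefix="", prefix_sep="").astype(float)
    if covariates is not None:
        for col in covariates.columns:
            d = pd.get_dummies(
                covariates[col].astype(str), prefix=col, prefix_sep="_", drop_first=True
            ).astype(float)
            d.index = design.index
            design = pd.concat([design, d], axis=1)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("design matrix is not of full column rank")
    return design


def group_contrast(
    design: pd.DataFrame,
    numerator: Sequence[str],
    denominator: Sequence[str],
) -> pd.Series:
    """Contrast mean(numerator groups) - mean(denominator groups)."""
    c = pd.Series(0.0, index=design.columns)
    for g in numerator:
        if g not in c.index:
            raise ValueError(f"unknown design column: {g!r}")
        c[g] += 1.0 / len(numerator)
    for g in denominator:
        if g not in c.index:
            raise ValueError(f"unknown design column: {g!r}")
        c[g] -= 1.0 / len(denominator)
    return c


# ---------------------------------------------------------------------------
# precision weights (mean-variance trend)


def mean_variance_weights(
    logcpm: pd.DataFrame, design: pd.DataFrame, span: float = 0.5
) -> pd.DataFrame:
    """Per-observation precision weights from the mean-variance trend.

    An ordinary fit per gene yields residual standard deviations; sqrt(sd)
    is smoothed against mean log-CPM by lowess (fraction ``span``), the
    trend is evaluated at each fitted value, and weights are the predicted
    standard deviation to the power -4.
    """
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more samples ({n}) than coefficients ({p})")
    Y = logcpm.to_numpy(dtype=float)

    pinv = np.linalg.pinv(X)
    beta = Y @ pinv.T  # genes x p
    fitted = beta @ X.T  # genes x n
    resid = Y - fitted
    sigma = np.sqrt((resid**2).sum(axis=1) / (n - p))

    sx = Y.mean(axis=1)
    sy = np.sqrt(sigma)
    trend = lowess(sy, sx, frac=span, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]
    floor = max(1e-4, ty[ty > 0].min() if (ty > 0).any() else 1e-4)
    pred_sqrt_sd = np.clip(np.interp(fitted, tx, ty), floor, None)
    w = pred_sqrt_sd**-4.0
    return pd.DataFrame(w, index=logcpm.index, columns=logcpm.columns)


# ---------------------------------------------------------------------------
# weighted fits + empirical-Bayes moderation


@dataclasses.dataclass
class GeneFits:
    """Per-gene weighted least-squares fits with moderated variances."""

    genes: pd.Index
    design_columns: pd.Index
    coefficients: np.ndarray  # genes x p
    xtwx_inv: np.ndarray  # genes x p x p (unscaled covariance of beta)
    sigma2: np.ndarray  # residual variances s_g^2
    df_residual: float
    prior_df: float  # d0
    prior_var: float  # s0^2
    ave_expr: np.ndarray  # mean log-CPM per gene

    @property
    def posterior_var(self) -> np.ndarray:
        d0, dg = self.prior_df, self.df_residual
        if d0 >= PRIOR_DF_CAP:
            return np.full_like(self.sigma2, self.prior_var)
        return (d0 * self.prior_var + dg * self.sigma2) / (d0 + dg)

    @property
    def df_total(self) -> float:
        return min(self.prior_df + self.df_residual, PRIOR_DF_CAP)


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if -dif / y < 1e-8:
            break
    return float(y)


def _moment_estimate_prior(sigma2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) on log residual variances."""
    ok = sigma2 > 0
    if not ok.any():
        raise ValueError("all genes have zero residual variance")
    z = np.log(sigma2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0) if len(e) > 1 else 0.0
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s02 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = PRIOR_DF_CAP
        s02 = np.exp(emean)
    return float(min(d0, PRIOR_DF_CAP)), float(s02)


def fit_and_moderate(
    logcpm: pd.DataFrame,
    weights: pd.DataFrame | None,
    design: pd.DataFrame,
    prior_df: float | None = None,
) -> GeneFits:
    """Weighted least squares per gene plus empirical-Bayes variance shrinkage.

    ``prior_df`` overrides the estimated d0 (0 disables moderation; values
    at or above the cap force complete shrinkage to the prior variance).
    """
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is not of full column rank")
    if n - p <= 0:
        raise ValueError("zero residual degrees of freedom")
    Y = logcpm.to_numpy(dtype=float)
    W = (
        np.ones_like(Y)
        if weights is None
        else weights.to_numpy(dtype=float)
    )
    if np.any(W <= 0):
        raise ValueError("weights must be strictly positive")

    xtwx = np.einsum("ni,gn,nj->gij", X, W, X)
    xtwy = np.einsum("ni,gn,gn->gi", X, W, Y)
    beta = np.linalg.solve(xtwx, xtwy[..., None])[..., 0]
    xtwx_inv = np.linalg.inv(xtwx)
    resid = Y - beta @ X.T
    sigma2 = (W * resid**2).sum(axis=1) / (n - p)

    d0, s02 = _moment_estimate_prior(sigma2, n - p)
    if prior_df is not None:
        d0 = float(min(prior_df, PRIOR_DF_CAP))
        if prior_df == 0:
            s02 = float(np.median(sigma2[sigma2 > 0]))  # unused when d0 = 0

    return GeneFits(
        genes=logcpm.index,
        design_columns=design.columns,
        coefficients=beta,
        xtwx_inv=xtwx_inv,
        sigma2=sigma2,
        df_residual=float(n - p),
        prior_df=d0,
        prior_var=s02,
        ave_expr=Y.mean(axis=1),
    )


# ---------------------------------------------------------------------------
# fold-change-thresholded moderated test


def treat_test(
    fits: GeneFits,
    contrast: pd.Series | np.ndarray,
    fc_threshold: float = 1.1,
) -> pd.DataFrame:
    """Moderated test of H0: |true log2FC| <= log2(fc_threshold).

    Returns a table with columns gene, logFC, AveExpr, t, P.Value,
    adj.P.Val; the ``tau`` attribute records the threshold in log2 units.
    """
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1")
    c = np.asarray(
        contrast.reindex(fits.design_columns).to_numpy()
        if isinstance(contrast, pd.Series)
        else contrast,
        dtype=float,
    )
    if c.shape != (len(fits.design_columns),):
        raise ValueError(
            f"contrast length {c.shape} does not match "
            f"{len(fits.design_columns)} coefficients"
        )
    tau = float(np.log2(fc_threshold))

    logfc = fits.coefficients @ c
    u = np.sqrt(np.einsum("i,gij,j->g", c, fits.xtwx_inv, c))
    se = np.sqrt(fits.posterior_var) * u
    df = fits.df_total

    t_right = (np.abs(logfc) - tau) / se
    t_left = (np.abs(logfc) + tau) / se
    p = stats.t.sf(t_right, df) + stats.t.sf(t_left, df)
    tstat = np.sign(logfc) * t_right

    out = pd.DataFrame(
        {
            "logFC": logfc,
            "AveExpr": fits.ave_expr,
            "t": tstat,
            "P.Value": p,
            "adj.P.Val": adjust_bh(p),
        },
        index=fits.genes,
    )
    out.attrs["tau"] = tau
    return out


def adjust_bh(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def decide_directions(results: pd.DataFrame, fdr: float = 0.05) -> pd.Series:
    """{-1, 0, +1} directional call per gene at the stated FDR (boundary inclusive)."""
    sig = results["adj.P.Val"] <= fdr
    d = np.where(sig, np.sign(results["logFC"]).astype(int), 0)
    return pd.Series(d, index=results.index, name="direction", dtype=int)


# ---------------------------------------------------------------------------
# QC embeddings


def qc_embeddings(
    logcpm: pd.DataFrame, top_genes: int = 500, n_components: int = 2
) -> dict[str, pd.DataFrame]:
    """PCA, leading-logFC MDS and relative-log-expression QC views."""
    n = logcpm.shape[1]
    if n < 3:
        raise ValueError("need at least three samples")
    if n_components >= n:
        raise ValueError("fewer samples than requested components")
    Y = logcpm.to_numpy(dtype=float)

    centered = Y - Y.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # fixed sign convention: the largest-|loading| entry of each axis positive
    for k in range(len(s)):
        i = np.argmax(np.abs(u[:, k]))
        if u[i, k] < 0:
            u[:, k] *= -1
            vt[k, :] *= -1
    pca = pd.DataFrame(
        (vt[:n_components].T * s[:n_components]),
        index=logcpm.columns,
        columns=[f"PC{k + 1}" for k in range(n_components)],
    )
    var_frac = s**2 / (s**2).sum()
    pca.attrs["variance_fraction"] = var_frac[:n_components]

    k = min(top_genes, Y.shape[0])
    dist = np.zeros((n, n))
    for i in range(n):
        diff2 = (Y[:, i][:, None] - Y[:, i + 1 :]) ** 2
        for jj in range(diff2.shape[1]):
            top = np.partition(diff2[:, jj], len(diff2) - k)[-k:]
            d = np.sqrt(top.mean())
            dist[i, i + 1 + jj] = dist[i + 1 + jj, i] = d
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (dist**2) @ J
    evals, evecs = np.linalg.eigh(B)
    idx = np.argsort(evals)[::-1][:n_components]
    coords = evecs[:, idx] * np.sqrt(np.clip(evals[idx], 0, None))
    mds = pd.DataFrame(
        coords, index=logcpm.columns, columns=[f"dim{k + 1}" for k in range(n_components)]
    )

    rle = logcpm.sub(logcpm.median(axis=1), axis=0)
    return {"pca": pca, "mds": mds, "rle": rle}
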