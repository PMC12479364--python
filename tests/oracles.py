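"""Independent loop-based oracles used to cross-check the vectorized code.

These deliberately avoid the library's implementations: explicit Python
loops, scalar arithmetic, and the formulas written out step by step.
"""

from __future__ import annotations

import numpy as np


def tmm_factor_pair_oracle(
    obs: np.ndarray,
    ref: np.ndarray,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> float:
    """Trimmed, precision-weighted mean of log-ratios for one sample pair."""
    lib_obs = float(sum(obs))
    lib_ref = float(sum(ref))
    m_vals, a_vals, v_vals = [], [], []
    for o, r in zip(obs, ref):
        if o > 0 and r > 0:
            po = o / lib_obs
            pr = r / lib_ref
            m_vals.append(np.log2(po / pr))
            a_vals.append((np.log2(po) + np.log2(pr)) / 2.0)
            v_vals.append((lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r))
    n = len(m_vals)
    if n == 0:
        raise ValueError("no shared positive genes")
    if max(abs(m) for m in m_vals) < 1e-6:
        return 1.0

    def ranks(vals):
        order = sorted(range(len(vals)), key=lambda i: vals[i])
        rk = [0.0] * len(vals)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and vals[order[j + 1]] == vals[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for t in range(i, j + 1):
                rk[order[t]] = avg
            i = j + 1
        return rk

    rm = ranks(m_vals)
    ra = ranks(a_vals)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    num = den = 0.0
    kept = False
    for i in range(n):
        if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a:
            num += m_vals[i] / v_vals[i]
            den += 1.0 / v_vals[i]
            kept = True
    if not kept:
        return 1.0
    f = num / den
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def tmm_factors_oracle(matrix: np.ndarray, trim_m: float = 0.30, trim_a: float = 0.05):
    """Full TMM: reference pick, per-sample pair factors, geometric-mean-1 rescale."""
    n_samples = matrix.shape[1]
    f75 = []
    for j in range(n_samples):
        col = matrix[:, j]
        f75.append(np.quantile(col, 0.75) / col.sum())
    mean75 = sum(f75) / len(f75)
    ref = min(range(n_samples), key=lambda j: abs(f75[j] - mean75))
    factors = [
        tmm_factor_pair_oracle(matrix[:, j], matrix[:, ref], trim_m, trim_a)
        for j in range(n_samples)
    ]
    log_gm = sum(np.log(f) for f in factors) / len(factors)
    return [f / np.exp(log_gm) for f in factors], ref


def rank_score_oracle(values, up_genes, gene_names):
    """Single-sample up-set score: sort, average-tie rank, mean, normalize."""
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    idx = [k for k, g in enumerate(gene_names) if g in set(up_genes)]
    n_up = len(idx)
    mean_rank = sum(ranks[k] for k in idx) / n_up
    lo = (n_up + 1) / 2.0
    hi = (2 * n - n_up + 1) / 2.0
    return (mean_rank - lo) / (hi - lo) - 0.5


def gsea_walk_oracle(stats_desc, hit_flags, weight_p):
    """Loop-based running-sum walk; returns the larger-magnitude extremum."""
    n = len(stats_desc)
    n_set = sum(hit_flags)
    hit_total = sum(abs(s) ** weight_p for s, h in zip(stats_desc, hit_flags) if h)
    running = 0.0
    best = 0.0
    for s, h in zip(stats_desc, hit_flags):
        if h:
            if hit_total > 0:
                running += abs(s) ** weight_p / hit_total
            else:
                running += 1.0 / n_set
        else:
            running -= 1.0 / (n - n_set)
        if abs(running) > abs(best) or (abs(running) == abs(best) and running > best):
            best = running
    return best


def bh_oracle(pvals):
    """Step-up BH executed literally: sort, scale, cumulative minimum."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    scaled = [pvals[order[i]] * n / (i + 1) for i in range(n)]
    out_sorted = [0.0] * n
    running_min = 1.0
    for i in range(n - 1, -1, -1):
        running_min = min(running_min, scaled[i])
        out_sorted[i] = min(running_min, 1.0)
    q = [0.0] * n
    for i in range(n):
        q[order[i]] = out_sorted[i]
    return q
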