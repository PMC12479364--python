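import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fhsig import bulk_de
from fhsig.io import CountMatrix

from oracles import bh_oracle, tmm_factors_oracle


def cm(values, genes=None, samples=None):
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return CountMatrix(pd.DataFrame(values, index=genes, columns=samples))


class TestReplicateSumming:
    def test_two_runs_sum_to_double(self, rng):
        vals = rng.integers(0, 50, size=(10, 3))
        runs = cm(np.hstack([vals, vals]), samples=[f"r{j}" for j in range(6)])
        groups = {f"r{j}": f"s{j % 3}" for j in range(6)}
        out = bulk_de.sum_technical_replicates(runs, groups)
        assert (out.values.to_numpy() == 2 * vals).all()

    def test_singleton_groups_identity(self, rng):
        m = cm(rng.integers(0, 50, size=(8, 4)))
        out = bulk_de.sum_technical_replicates(m, {s: s for s in m.sample_ids})
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_unassigned_sample_errors(self, rng):
        m = cm(rng.integers(0, 50, size=(8, 4)))
        with pytest.raises(ValueError, match="not assigned"):
            bulk_de.sum_technical_replicates(m, {"s0": "a"})


class TestLibrarySizeFilter:
    def test_small_library_dropped(self):
        m = cm(np.array([[1_200_000, 900_000]]))
        out = bulk_de.filter_samples_by_library_size(m)
        assert list(out.sample_ids) == ["s0"]

    def test_exactly_one_million_retained(self):
        m = cm(np.array([[1_000_000, 2_000_000]]))
        out = bulk_de.filter_samples_by_library_size(m)
        assert list(out.sample_ids) == ["s0", "s1"]

    def test_zero_threshold_identity(self, rng):
        m = cm(rng.integers(0, 50, size=(5, 3)))
        out = bulk_de.filter_samples_by_library_size(m, min_reads=0)
        pd.testing.assert_frame_equal(out.values, m.values)


class TestLowExpressionFilter:
    def test_hand_example_kept(self):
        """CPM 12 in the 2 smallest-group samples, total 24 >= 15 -> kept."""
        vals = np.zeros((4, 4), dtype=int)
        vals[0] = [12, 12, 0, 0]
        vals[1:] = 250_000  # pad library sizes to ~1e6
        m = cm(vals)
        out = bulk_de.filter_low_expression(m, ["A", "A", "B", "B"])
        assert "g0" in out.values.index

    def test_all_zero_gene_removed(self):
        vals = np.vstack([np.zeros(4, dtype=int), np.full((3, 4), 100_000)])
        out = bulk_de.filter_low_expression(cm(vals), ["A", "A", "B", "B"])
        assert "g0" not in out.values.index

    def test_below_min_total_removed(self):
        vals = np.vstack([np.array([14, 0, 0, 0]), np.full((3, 4), 100_000)])
        out = bulk_de.filter_low_expression(cm(vals), ["A", "A", "B", "B"])
        assert "g0" not in out.values.index

    def test_empty_group_errors(self, rng):
        m = cm(rng.integers(0, 50, size=(5, 2)))
        with pytest.raises(ValueError):
            bulk_de.filter_low_expression(m, [])


class TestTmm:
    def test_identical_columns_unit_factors(self, rng):
        col = rng.integers(1, 100, size=40)
        f = bulk_de.tmm_factors(cm(np.column_stack([col, col])))
        np.testing.assert_allclose(f.to_numpy(), [1.0, 1.0])

    def test_exact_scaling_unit_factors(self, rng):
        col = rng.integers(1, 100, size=40)
        f = bulk_de.tmm_factors(cm(np.column_stack([col, 3 * col])))
        np.testing.assert_allclose(f.to_numpy(), [1.0, 1.0])

    def test_matches_loop_oracle(self, rng):
        """Vectorized TMM equals the independent loop-based formula to 1e-12."""
        for _ in range(25):
            mat = rng.integers(0, 400, size=(50, 6))
            mat[rng.random(mat.shape) < 0.1] = 0
            got = bulk_de.tmm_factors(cm(mat)).to_numpy()
            want, _ = tmm_factors_oracle(mat.astype(float))
            np.testing.assert_allclose(got, want, rtol=0, atol=1e-12)

    def test_geometric_mean_one(self, rng):
        f = bulk_de.tmm_factors(cm(rng.integers(1, 500, size=(80, 5))))
        assert abs(np.exp(np.mean(np.log(f))) - 1.0) < 1e-9

    def test_disjoint_support_errors(self):
        mat = np.array([[5, 0], [6, 0], [0, 7], [0, 8]])
        with pytest.raises(ValueError, match="positive genes"):
            bulk_de.tmm_factors(cm(mat))


class TestLogCpm:
    def test_hand_value_zero_count(self):
        m = cm(np.array([[0], [1_000_000]]))
        factors = pd.Series([1.0], index=["s0"])
        # library 999999 + 1 = 1e6; log2(0.5 / (1e6+1) * 1e6)
        got = bulk_de.log_cpm(m, factors, prior=0.5).iloc[0, 0]
        want = np.log2(0.5 / (1e6 + 1) * 1e6)
        assert abs(got - want) < 1e-12

    def test_doubling_invariance_prior_zero(self):
        a = cm(np.array([[100], [900]]))
        b = cm(np.array([[200], [1800]]))
        f = pd.Series([1.0], index=["s0"])
        va = bulk_de.log_cpm(a, f, prior=0.0)
        vb = bulk_de.log_cpm(b, f, prior=0.0)
        np.testing.assert_allclose(va.to_numpy(), vb.to_numpy())

    def test_inverts_definition(self):
        # y = L * 1e-6 * 2^k with prior 0 -> value k
        L, k = 4_000_000, 3.0
        y = int(L * 1e-6 * 2**k)
        m = cm(np.array([[y], [L - y]]))
        f = pd.Series([1.0], index=["s0"])
        assert abs(bulk_de.log_cpm(m, f, prior=0.0).iloc[0, 0] - k) < 1e-9


class TestWeights:
    def test_homoskedastic_weights_flat(self, rng):
        y = pd.DataFrame(rng.normal(5, 1, size=(300, 8)))
        design = bulk_de.group_design(["a"] * 4 + ["b"] * 4)
        design.index = y.columns
        w = bulk_de.mean_variance_weights(y, design)
        assert (w.to_numpy() > 0).all()
        assert w.to_numpy().max() / w.to_numpy().min() < 2

    def test_weights_track_decreasing_variance(self, rng):
        """Counts-like data: variance falls with the mean, weights rise with it."""
        means = np.linspace(1, 10, 400)
        sds = 2.0 / np.sqrt(means)
        y = pd.DataFrame(rng.normal(means[:, None], sds[:, None], size=(400, 8)))
        design = bulk_de.group_design(["a"] * 4 + ["b"] * 4)
        design.index = y.columns
        w = bulk_de.mean_variance_weights(y, design)
        rho = stats.spearmanr(y.to_numpy().ravel(), w.to_numpy().ravel()).statistic
        assert rho > 0.5

    def test_underdetermined_design_errors(self, rng):
        y = pd.DataFrame(rng.normal(size=(10, 2)))
        design = bulk_de.group_design(["a", "b"])
        with pytest.raises(ValueError, match="samples"):
            bulk_de.mean_variance_weights(y, design)


def wls_ordinary_t(y, w, X, c):
    """Loop-based weighted least squares t statistic for one gene."""
    W = np.diag(w)
    xtwx = X.T @ W @ X
    beta = np.linalg.solve(xtwx, X.T @ W @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    s2 = float(resid @ W @ resid) / df
    se = np.sqrt(s2 * float(c @ np.linalg.solve(xtwx, c)))
    return float(c @ beta) / se


class TestModeration:
    def make_fit(self, rng, prior_df=None):
        y = pd.DataFrame(rng.normal(5, 1, size=(200, 6)))
        w = pd.DataFrame(rng.uniform(0.5, 2.0, size=(200, 6)))
        design = bulk_de.group_design(["a"] * 3 + ["b"] * 3)
        design.index = y.columns
        w.columns = y.columns
        return y, w, design, bulk_de.fit_and_moderate(y, w, design, prior_df=prior_df)

    def test_zero_prior_df_reduces_to_ordinary_t(self, rng):
        y, w, design, fits = self.make_fit(rng, prior_df=0)
        c = bulk_de.group_contrast(design, ["a"], ["b"]).to_numpy()
        res = bulk_de.treat_test(fits, c, fc_threshold=1.0)
        X = design.to_numpy()
        for g in [0, 17, 123, 199]:
            t_ref = wls_ordinary_t(
                y.iloc[g].to_numpy(), w.iloc[g].to_numpy(), X, c
            )
            assert abs(res["t"].iloc[g] - t_ref) < 1e-12

    def test_posterior_variance_formula(self):
        # s2 = 1, d_g = 4, d0 = 4, s0^2 = 2 -> posterior (4*2 + 4*1)/8 = 1.5
        fits = bulk_de.GeneFits(
            genes=pd.Index(["g"]),
            design_columns=pd.Index(["a"]),
            coefficients=np.array([[0.0]]),
            xtwx_inv=np.array([[[1.0]]]),
            sigma2=np.array([1.0]),
            df_residual=4.0,
            prior_df=4.0,
            prior_var=2.0,
            ave_expr=np.array([0.0]),
        )
        assert fits.posterior_var[0] == pytest.approx(1.5, abs=1e-15)

    def test_posterior_is_convex_combination(self, rng):
        _, _, _, fits = self.make_fit(rng)
        lo = np.minimum(fits.sigma2, fits.prior_var)
        hi = np.maximum(fits.sigma2, fits.prior_var)
        post = fits.posterior_var
        assert ((post >= lo - 1e-12) & (post <= hi + 1e-12)).all()

    def test_equal_variances_estimated_prior_matches(self, rng):
        """With a tight variance distribution s0^2 lands near it and shrinkage is mild."""
        y = pd.DataFrame(rng.normal(0, 2.0, size=(2000, 20)))
        design = bulk_de.group_design(["a"] * 10 + ["b"] * 10)
        design.index = y.columns
        fits = bulk_de.fit_and_moderate(y, None, design)
        assert abs(fits.prior_var - 4.0) / 4.0 < 0.1
        assert np.median(np.abs(fits.posterior_var - fits.sigma2) / fits.sigma2) < 0.5


class TestTreat:
    def make(self, rng):
        y = pd.DataFrame(rng.normal(5, 1, size=(300, 8)))
        design = bulk_de.group_design(["a"] * 4 + ["b"] * 4)
        design.index = y.columns
        fits = bulk_de.fit_and_moderate(y, None, design)
        c = bulk_de.group_contrast(design, ["a"], ["b"])
        return fits, c

    def test_threshold_one_equals_moderated_t(self, rng):
        fits, c = self.make(rng)
        res = bulk_de.treat_test(fits, c, fc_threshold=1.0)
        cv = c.to_numpy()
        logfc = fits.coefficients @ cv
        se = np.sqrt(fits.posterior_var) * np.sqrt(
            np.einsum("i,gij,j->g", cv, fits.xtwx_inv, cv)
        )
        p_ref = 2 * stats.t.sf(np.abs(logfc / se), fits.df_total)
        assert np.max(np.abs(res["P.Value"].to_numpy() - p_ref)) < 1e-10

    def test_boundary_logfc_gives_half_or_more(self, rng):
        fits, c = self.make(rng)
        tau = np.log2(1.1)
        cv = c.to_numpy()
        # force one gene's logFC to sit exactly on the threshold
        fits.coefficients[0] = 0.0
        fits.coefficients[0, 0] = tau  # contrast (a - b) picks this up as tau
        res = bulk_de.treat_test(fits, c, fc_threshold=1.1)
        assert res["P.Value"].iloc[0] >= 0.5

    def test_p_monotone_in_threshold(self, rng):
        fits, c = self.make(rng)
        p1 = bulk_de.treat_test(fits, c, fc_threshold=1.0)["P.Value"]
        p2 = bulk_de.treat_test(fits, c, fc_threshold=1.2)["P.Value"]
        p3 = bulk_de.treat_test(fits, c, fc_threshold=1.5)["P.Value"]
        assert (p2 >= p1 - 1e-12).all() and (p3 >= p2 - 1e-12).all()

    def test_contrast_length_mismatch(self, rng):
        fits, _ = self.make(rng)
        with pytest.raises(ValueError, match="contrast length"):
            bulk_de.treat_test(fits, np.array([1.0, -1.0, 0.0]))


class TestBh:
    def test_hand_example(self):
        got = bulk_de.adjust_bh([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bulk_de.adjust_bh([0.3]), [0.3])

    def test_matches_loop_oracle_and_order(self, rng):
        p = rng.uniform(size=200)
        q = bulk_de.adjust_bh(p)
        np.testing.assert_allclose(q, bh_oracle(list(p)), atol=1e-15)
        order_p = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order_p]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bulk_de.adjust_bh([0.5, 1.5])


class TestDirections:
    @pytest.mark.parametrize(
        "q,logfc,want",
        [(0.01, 0.8, 1), (0.2, 0.8, 0), (0.05, -0.3, -1), (0.050001, 1.0, 0)],
    )
    def test_call_rules(self, q, logfc, want):
        res = pd.DataFrame({"adj.P.Val": [q], "logFC": [logfc]}, index=["g"])
        assert bulk_de.decide_directions(res).iloc[0] == want


class TestQcEmbeddings:
    def test_duplicated_samples_coincide(self, rng):
        y = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("abcd"))
        y["d"] = y["a"]
        out = bulk_de.qc_embeddings(y)
        np.testing.assert_allclose(
            out["pca"].loc["a"].to_numpy(), out["pca"].loc["d"].to_numpy(), atol=1e-9
        )
        np.testing.assert_allclose(
            out["mds"].loc["a"].to_numpy(), out["mds"].loc["d"].to_numpy(), atol=1e-9
        )

    def test_separated_groups_split_on_pc1(self, rng):
        from sklearn.metrics import silhouette_score

        base = rng.normal(0, 1, size=(200, 8))
        base[:50, 4:] += 6  # half the genes shifted in the second group
        y = pd.DataFrame(base)
        out = bulk_de.qc_embeddings(y)
        labels = [0] * 4 + [1] * 4
        s = silhouette_score(out["pca"][["PC1"]].to_numpy(), labels)
        assert s > 0.5

    def test_rle_of_identical_columns_is_zero(self):
        y = pd.DataFrame(np.tile(np.arange(10.0)[:, None], (1, 4)))
        out = bulk_de.qc_embeddings(y)
        assert np.allclose(out["rle"].to_numpy(), 0.0)
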