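import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from fhsig import sc_pipeline as sc
from fhsig import synthetic
from fhsig.io import CountMatrix


def cell_matrix(values, genes=None):
    values = np.asarray(values)
    genes = genes or [f"g{j}" for j in range(values.shape[1])]
    return CountMatrix(
        pd.DataFrame(
            values, index=[f"c{i}" for i in range(values.shape[0])], columns=genes
        ),
        "cells_by_genes",
    )


class TestQc:
    def mito_cells(self, fractions, total=1000):
        rows = []
        for f in fractions:
            rows.append([int(total * f), int(total * (1 - f))])
        return cell_matrix(rows, genes=["mt-nd1", "actb"])

    @pytest.mark.parametrize(
        "frac,removed", [(0.25, True), (0.19, False), (0.20, True)]
    )
    def test_mito_boundary_inclusive(self, frac, removed):
        cells = self.mito_cells([frac, 0.01, 0.01, 0.01])
        filtered, qc = sc.qc_filter_cells(cells, count_quantile=0.0)
        assert ("c0" not in filtered.values.index) == removed

    def test_equal_totals_quantile_removes_none(self):
        cells = self.mito_cells([0.01] * 8)
        filtered, _ = sc.qc_filter_cells(cells, count_quantile=0.10)
        assert filtered.shape[0] == 8

    def test_quantile_hand_example(self):
        """Totals 1..10, 10th percentile (type 7) = 1.9: only the total-1 cell drops."""
        vals = [[t, 0] for t in range(1, 11)]
        cells = cell_matrix(vals, genes=["a", "b"])
        filtered, qc = sc.qc_filter_cells(
            cells, mito_max=1.1, count_quantile=0.10, require_mito_genes=False
        )
        assert set(cells.values.index) - set(filtered.values.index) == {"c0"}

    def test_missing_mito_genes_error(self):
        cells = cell_matrix([[5, 5]], genes=["a", "b"])
        with pytest.raises(ValueError, match="mitochondrial"):
            sc.qc_filter_cells(cells)


class TestNormalize:
    def test_scaling_a_cell_preserves_profile(self):
        base = np.array([[10, 20, 30], [5, 10, 5], [8, 2, 10], [3, 9, 8]])
        doubled = base.copy()
        doubled[0] *= 2
        a = sc.lognormalize_cells(cell_matrix(base))
        b = sc.lognormalize_cells(cell_matrix(doubled))
        np.testing.assert_allclose(a.iloc[0].to_numpy(), b.iloc[0].to_numpy())

    def test_equal_cells_reduce_to_log2_plus_one(self):
        vals = np.tile([4, 8, 12], (5, 1))
        out = sc.lognormalize_cells(cell_matrix(vals))
        np.testing.assert_allclose(out.iloc[0].to_numpy(), np.log2(np.array([4, 8, 12]) + 1))

    def test_two_cell_median_rule(self):
        """Totals (100, 200): median 150, size factors (2/3, 4/3)."""
        vals = np.array([[60, 40], [120, 80]])
        out = sc.lognormalize_cells(cell_matrix(vals))
        np.testing.assert_allclose(
            out.iloc[0].to_numpy(), np.log2(np.array([60, 40]) / (100 / 150) + 1)
        )
        np.testing.assert_allclose(
            out.iloc[1].to_numpy(), np.log2(np.array([120, 80]) / (200 / 150) + 1)
        )

    def test_zero_total_cell_errors(self):
        with pytest.raises(ValueError, match="zero-total"):
            sc.lognormalize_cells(cell_matrix([[0, 0], [1, 2]]))


class TestHvgs:
    def test_constant_gene_never_selected(self, rng):
        df = pd.DataFrame(
            {"var1": rng.normal(size=20), "const": 1.0, "var2": rng.normal(size=20)}
        )
        assert sc.select_hvgs(df, n=2) == sorted(
            ["var1", "var2"], key=lambda g: (-df[g].var(ddof=1), g)
        )

    def test_length_capped(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 4)))
        assert len(sc.select_hvgs(df, n=100)) == 4

    def test_hand_ordering(self):
        df = pd.DataFrame(
            {
                "a": [0.0, 4.0],  # var 8
                "b": [0.0, 2.0],  # var 2
                "c": [0.0, 6.0],  # var 18
            }
        )
        assert sc.select_hvgs(df, n=3) == ["c", "a", "b"]


class TestPca:
    def test_rank_one_data(self, rng):
        u = rng.normal(size=50)
        v = rng.normal(size=8)
        df = pd.DataFrame(np.outer(u, v))
        emb = sc.pca_cells(df, n_components=3)
        assert emb.attrs["variance_fraction"][0] > 0.999

    def test_duplicated_cells_coincide(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 6)))
        df.iloc[5] = df.iloc[2]
        emb = sc.pca_cells(df, n_components=3)
        np.testing.assert_allclose(
            emb.iloc[5].to_numpy(), emb.iloc[2].to_numpy(), atol=1e-9
        )

    def test_two_blobs_separate(self, rng):
        from sklearn.metrics import silhouette_score

        df = pd.DataFrame(rng.normal(size=(60, 10)))
        df.iloc[:30] += 5
        emb = sc.pca_cells(df, n_components=2)
        assert silhouette_score(emb[["PC1"]], [0] * 30 + [1] * 30) > 0.5


class TestKnnJaccard:
    def test_hand_weight(self):
        emb = pd.DataFrame({"x": [0.0, 1.0, 2.0, 10.0], "y": 0.0}, index=list("ABCD"))
        g = sc.knn_jaccard_graph(emb, k=2)
        # N(A)={B,C}, N(B)={A,C}: intersection {C}, union {A,B,C} -> 1/3
        assert g.edges["A", "B"]["weight"] == pytest.approx(1 / 3)

    def test_weights_in_unit_interval(self, rng):
        emb = pd.DataFrame(rng.normal(size=(40, 3)))
        g = sc.knn_jaccard_graph(emb, k=5)
        ws = [d["weight"] for _, _, d in g.edges(data=True)]
        assert all(0 < w <= 1 for w in ws)

    def test_separated_blobs_no_cross_edges(self, rng):
        emb = pd.DataFrame(rng.normal(size=(40, 2)))
        emb.iloc[20:] += 100
        g = sc.knn_jaccard_graph(emb, k=4)
        for a, b in g.edges:
            assert (a < 20) == (b < 20)

    def test_k_too_large_errors(self, rng):
        emb = pd.DataFrame(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError):
            sc.knn_jaccard_graph(emb, k=5)


class TestLouvain:
    def test_two_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        labels = sc.louvain_communities(g, seed=0)
        assert labels.nunique() == 2
        assert labels.iloc[:5].nunique() == 1 and labels.iloc[5:].nunique() == 1

    def test_determinism(self, rng):
        g = nx.gnm_random_graph(60, 200, seed=4)
        a = sc.louvain_communities(g, seed=11)
        b = sc.louvain_communities(g, seed=11)
        pd.testing.assert_series_equal(a, b)

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError):
            sc.louvain_communities(nx.Graph())


class TestPseudobulk:
    def meta(self, cells, clusters, samples):
        return pd.DataFrame(
            {"cluster": clusters, "sample": samples}, index=cells.values.index
        )

    def test_single_group_column_sums(self, rng):
        cells = cell_matrix(rng.integers(0, 20, size=(12, 5)))
        meta = self.meta(cells, ["k1"] * 12, ["s1"] * 12)
        pb, pbm = sc.pseudobulk(cells, meta, min_cells=1)
        np.testing.assert_array_equal(
            pb.as_genes_by_samples().iloc[:, 0].to_numpy(),
            cells.values.sum(axis=0).to_numpy(),
        )
        assert pbm["n_cells"].iloc[0] == 12

    def test_group_below_cutoff_dropped(self, rng):
        cells = cell_matrix(rng.integers(0, 20, size=(19, 4)))
        meta = self.meta(cells, ["a"] * 9 + ["b"] * 10, ["s"] * 19)
        pb, pbm = sc.pseudobulk(cells, meta, min_cells=10)
        assert list(pbm["cluster"]) == ["b"]

    def test_hand_sums(self):
        cells = cell_matrix([[1, 2], [3, 4], [5, 6], [7, 8]])
        meta = self.meta(cells, ["x", "x", "y", "y"], ["s"] * 4)
        pb, _ = sc.pseudobulk(cells, meta, min_cells=1)
        gxs = pb.as_genes_by_samples()
        np.testing.assert_array_equal(gxs["x|s"].to_numpy(), [4, 6])
        np.testing.assert_array_equal(gxs["y|s"].to_numpy(), [12, 14])

    def test_sums_are_exact_partition(self, sc_run):
        cells = sc_run["cells"]
        meta = sc_run["meta"].assign(cluster=sc_run["truth"].cell_clusters)
        pb, pbm = sc.pseudobulk(cells, meta, by=["cluster"], min_cells=1)
        np.testing.assert_array_equal(
            pb.as_genes_by_samples().sum(axis=1).to_numpy(),
            cells.values.sum(axis=0).to_numpy(),
        )


class TestPseudobulkDe:
    def test_confounded_donor_errors(self, rng):
        pbvals = rng.integers(100, 1000, size=(50, 4))
        pb = CountMatrix(
            pd.DataFrame(pbvals, index=[f"g{i}" for i in range(50)], columns=list("abcd"))
        )
        meta = pd.DataFrame(
            {"cluster": ["k1", "k1", "k2", "k2"], "donor": ["d1", "d1", "d2", "d2"]},
            index=list("abcd"),
        )
        with pytest.raises(ValueError, match="confounded"):
            sc.pseudobulk_de(pb, meta, "cluster", "k1", "k2", donor_col="donor")

    def test_null_contrast_makes_no_calls(self, rng):
        """Groups drawn from one distribution: essentially nothing passes FDR."""
        lam = rng.uniform(50, 500, size=300)
        vals = rng.poisson(lam[:, None], size=(300, 6))
        pb = CountMatrix(
            pd.DataFrame(vals, index=[f"g{i}" for i in range(300)],
                         columns=[f"s{j}" for j in range(6)])
        )
        meta = pd.DataFrame(
            {"cluster": ["k1"] * 3 + ["k2"] * 3, "donor": ["d1", "d2", "d3"] * 2},
            index=pb.sample_ids,
        )
        res = sc.pseudobulk_de(pb, meta, "cluster", "k1", "k2", donor_col="donor")
        assert (res["adj.P.Val"] <= 0.05).mean() < 0.02


class TestClr:
    def test_hand_example(self):
        out = sc.clr_normalize_protein(pd.DataFrame([[1, 3]], columns=["p1", "p2"]))
        np.testing.assert_allclose(
            out.to_numpy(), [[-0.34657359, 0.34657359]], atol=1e-6
        )

    def test_rows_sum_to_zero(self, rng):
        counts = pd.DataFrame(rng.integers(0, 100, size=(30, 6)))
        out = sc.clr_normalize_protein(counts)
        np.testing.assert_allclose(out.sum(axis=1).to_numpy(), 0, atol=1e-9)

    def test_constant_vector_zeros(self):
        out = sc.clr_normalize_protein(pd.DataFrame([[5, 5, 5]]))
        np.testing.assert_allclose(out.to_numpy(), 0, atol=1e-12)


class TestEndToEndClustering:
    def test_planted_clusters_recovered(self, sc_run):
        cells = sc_run["cells"]
        filtered, _ = sc.qc_filter_cells(cells)
        norm = sc.lognormalize_cells(filtered)
        hvgs = sc.select_hvgs(norm, n=500)
        emb = sc.pca_cells(norm, hvgs, n_components=20)
        graph = sc.knn_jaccard_graph(emb, k=9)
        labels = sc.louvain_communities(graph, seed=3)
        truth = sc_run["truth"].cell_clusters.loc[labels.index]
        assert adjusted_rand_score(truth, labels) >= 0.9
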