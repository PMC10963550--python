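import numpy as np
import pandas as pd
import pytest

import tmehot as th
from tmehot.datatypes import ExpressionMatrix


def make_counts(columns: dict[str, list[float]], genes=None) -> ExpressionMatrix:
    df = pd.DataFrame(columns)
    df.index = genes if genes is not None else [f"g{i}" for i in range(len(df))]
    return ExpressionMatrix(df, lognorm=False)


class TestQCFilter:
    @pytest.fixture
    def counts(self):
        """600-gene matrix; g0 is the mitochondrial gene.

        cell_low       150 detected genes               -> removed (< 200)
        cell_ok        501 detected, 25/525 = 4.8% mito -> retained
        cell_mito20    401 detected, 100/500 = 20% mito -> removed (> 15%)
        cell_mito15    341 detected,  60/400 = 15% mito -> retained (boundary)
        cell_min200    exactly 200 detected             -> retained (boundary)
        """
        n = 600
        idx = [f"g{i}" for i in range(n)]
        df = pd.DataFrame(0.0, index=idx, columns=[])
        col = np.zeros(n); col[1:151] = 1
        df["cell_low"] = col
        col = np.zeros(n); col[1:501] = 1; col[0] = 25
        df["cell_ok"] = col
        col = np.zeros(n); col[1:401] = 1; col[0] = 100
        df["cell_mito20"] = col
        col = np.zeros(n); col[1:341] = 1; col[0] = 60
        df["cell_mito15"] = col
        col = np.zeros(n); col[1:201] = 1
        df["cell_min200"] = col
        return df

    def test_thresholds(self, counts):
        out = th.qc_filter(ExpressionMatrix(counts), mito_genes=["g0"])
        assert "cell_ok" in out.units
        assert "cell_low" not in out.units
        assert "cell_mito20" not in out.units

    def test_boundaries_inclusive(self, counts):
        out = th.qc_filter(ExpressionMatrix(counts), mito_genes=["g0"])
        assert "cell_mito15" in out.units  # exactly 15% mito retained
        assert "cell_min200" in out.units  # exactly 200 detected retained

    def test_retained_values_unchanged(self, counts):
        em = ExpressionMatrix(counts)
        out = th.qc_filter(em, mito_genes=["g0"])
        for cell in out.units:
            pd.testing.assert_series_equal(out.data[cell], em.data[cell])
        assert list(out.genes) == list(em.genes)

    def test_all_cells_removed_warns(self):
        df = pd.DataFrame(
            {"c1": [1, 0, 0], "c2": [0, 1, 0]}, index=["g0", "g1", "g2"]
        )
        with pytest.warns(UserWarning, match="every cell"):
            out = th.qc_filter(ExpressionMatrix(df), mito_genes=[])
        assert out.shape[1] == 0

    def test_empty_matrix_rejected(self):
        df = pd.DataFrame(index=["g0", "g1"])
        with pytest.raises(ValueError):
            th.qc_filter(ExpressionMatrix(df), mito_genes=[])


class TestLognormalize:
    def test_totals_already_at_scale(self):
        em = make_counts({"c1": [10, 0, 90]})
        out = th.lognormalize(em, scale_total=100)
        np.testing.assert_allclose(out.data["c1"], np.log1p([10, 0, 90]))
        assert out.lognorm

    def test_zero_total_cell_named(self):
        em = make_counts({"good": [1, 2, 3], "empty": [0, 0, 0]})
        with pytest.raises(ValueError, match="empty"):
            th.lognormalize(em)

    def test_scale_invariance(self):
        em1 = make_counts({"c1": [10, 5, 85]})
        em2 = make_counts({"c1": [20, 10, 170]})
        out1 = th.lognormalize(em1)
        out2 = th.lognormalize(em2)
        pd.testing.assert_frame_equal(out1.data, out2.data)

    def test_expm1_column_sums_equal_scale(self):
        em = make_counts({"c1": [3, 7, 11], "c2": [1, 1, 1]})
        out = th.lognormalize(em, scale_total=1e4)
        np.testing.assert_allclose(np.expm1(out.data).sum(axis=0), 1e4)


class TestFindMarkers:
    def test_planted_markers_significant(self, small_atlas):
        expr, ann, truth = small_atlas
        mt = th.find_markers(th.lognormalize(expr), ann)
        for cluster, markers in truth.planted_markers.items():
            sub = mt[mt["cluster"] == cluster].set_index("gene")
            found = [g for g in markers if g in sub.index]
            assert len(found) >= 9  # at least 9/10 planted markers tabled
            assert (sub.loc[found, "log2_fold_change"] > 0).all()
            assert (sub.loc[found, "p_adjusted"] < 0.05).all()

    def test_constant_gene_excluded(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.uniform(0, 2, size=(5, 20)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"c{i}" for i in range(20)],
        )
        df.loc["g0"] = 1.0  # identical in all cells
        ann = pd.DataFrame(
            {"cluster": ["a"] * 10 + ["b"] * 10, "lineage": "other"},
            index=df.columns,
        )
        mt = th.find_markers(ExpressionMatrix(df, lognorm=True), ann)
        assert "g0" not in set(mt["gene"])

    def test_label_swap_equivariance(self, small_atlas):
        expr, ann, _ = small_atlas
        lognorm = th.lognormalize(expr)
        mt = th.find_markers(lognorm, ann)
        swapped = ann.copy()
        swap = {"cluster_1": "cluster_2", "cluster_2": "cluster_1"}
        swapped["cluster"] = ann["cluster"].map(lambda c: swap.get(c, c))
        mt_sw = th.find_markers(lognorm, swapped)

        def table(m, c):
            return (
                m[m["cluster"] == c]
                .drop(columns="cluster")
                .sort_values("gene")
                .reset_index(drop=True)
            )

        pd.testing.assert_frame_equal(table(mt, "cluster_1"), table(mt_sw, "cluster_2"))
        pd.testing.assert_frame_equal(table(mt, "cluster_3"), table(mt_sw, "cluster_3"))

    def test_cell_order_invariance(self, small_atlas):
        expr, ann, _ = small_atlas
        lognorm = th.lognormalize(expr)
        rng = np.random.default_rng(1)
        perm = rng.permutation(lognorm.data.columns)
        shuffled = ExpressionMatrix(lognorm.data[perm], lognorm=True)
        mt1 = th.find_markers(lognorm, ann).sort_values(["cluster", "gene"]).reset_index(drop=True)
        mt2 = th.find_markers(shuffled, ann.loc[perm]).sort_values(["cluster", "gene"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(mt1, mt2)

    def test_single_cell_cluster_rejected(self):
        df = pd.DataFrame(
            np.ones((3, 5)), index=["g0", "g1", "g2"], columns=[f"c{i}" for i in range(5)]
        )
        ann = pd.DataFrame(
            {"cluster": ["a", "a", "a", "a", "b"], "lineage": "other"}, index=df.columns
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            th.find_markers(ExpressionMatrix(df, lognorm=True), ann)

    def test_unknown_cells_rejected(self, small_atlas):
        expr, ann, _ = small_atlas
        bad = ann.copy()
        bad.index = ["ghost"] + list(ann.index[1:])
        with pytest.raises(ValueError, match="absent"):
            th.find_markers(th.lognormalize(expr), bad)


class TestTopMarkers:
    @pytest.fixture
    def marker_table(self):
        return pd.DataFrame(
            {
                "cluster": ["a"] * 4 + ["b"] * 2,
                "gene": ["g1", "g2", "g3", "g4", "g5", "g6"],
                "log2_fold_change": [2.0, 2.0, 1.5, 1.0, 3.0, 0.5],
                "frac_expr_in": 0.5,
                "frac_expr_out": 0.1,
                "p_value": [1e-3, 1e-5, 1e-4, 1e-2, 1e-6, 1e-1],
                "p_adjusted": [1e-2, 1e-4, 1e-3, 1e-1, 1e-5, 1.0],
            }
        )

    def test_counts_capped_and_short_lists(self, marker_table):
        assert len(th.top_markers(marker_table, "a", 3)) == 3
        assert th.top_markers(marker_table, "b", 15) == ["g5", "g6"]

    def test_tie_breaks_by_smaller_p(self, marker_table):
        top = th.top_markers(marker_table, "a", 2)
        assert top == ["g2", "g1"]  # tied fold change, 1e-5 beats 1e-3

    def test_unknown_cluster(self, marker_table):
        with pytest.raises(KeyError):
            th.top_markers(marker_table, "zz", 5)
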