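import numpy as np
import pandas as pd
import pytest

import tmehot as th
from tmehot.datatypes import ExpressionMatrix

from .oracles import logrank_oracle, ranksum_exact_p


def expr_from(rows: dict[str, list[float]]) -> ExpressionMatrix:
    df = pd.DataFrame(rows).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return ExpressionMatrix(df, lognorm=True)


class TestCorrelate:
    def test_perfect_and_negated_correlation(self):
        score = pd.Series([1.0, 2.0, 3.0, 4.0], index=[f"s{i}" for i in range(4)])
        expr = expr_from({"same": [1, 2, 3, 4], "anti": [4, 3, 2, 1]})
        out = th.correlate_with_score(expr, score).set_index("gene")
        assert out.loc["same", "pearson_r"] == pytest.approx(1.0)
        assert out.loc["same", "p_correlation"] < 1e-6
        assert out.loc["anti", "pearson_r"] == pytest.approx(-1.0)

    def test_constant_gene_flagged_not_dropped(self):
        score = pd.Series([1.0, 2.0, 3.0], index=["s0", "s1", "s2"])
        expr = expr_from({"flat": [2, 2, 2], "ok": [1, 2, 4]})
        out = th.correlate_with_score(expr, score).set_index("gene")
        assert out.loc["flat", "undefined"]
        assert np.isnan(out.loc["flat", "pearson_r"])
        assert not out.loc["ok", "undefined"]

    def test_too_few_samples(self):
        score = pd.Series([1.0, 2.0], index=["s0", "s1"])
        expr = expr_from({"g": [1, 2]})
        with pytest.raises(ValueError, match="3 samples"):
            th.correlate_with_score(expr, score)


class TestCoxFit:
    def test_recovers_planted_log_hr(self):
        rng = np.random.default_rng(0)
        x = pd.Series(rng.normal(size=500), index=[f"s{i}" for i in range(500)], name="x")
        surv = th.simulate_survival(x, -0.5, 0.05, 0.2, seed=3)
        fit = th.cox_fit(surv, "x")
        assert fit.loc[0, "beta"] == pytest.approx(-0.5, abs=0.15)
        assert fit.loc[0, "hazard_ratio"] == pytest.approx(np.exp(fit.loc[0, "beta"]))
        assert fit.loc[0, "ci_low"] < fit.loc[0, "hazard_ratio"] < fit.loc[0, "ci_high"]

    def test_multivariate_fit(self):
        rng = np.random.default_rng(1)
        n = 400
        idx = [f"s{i}" for i in range(n)]
        x1 = pd.Series(rng.normal(size=n), index=idx, name="x1")
        surv = th.simulate_survival(x1, -0.5, 0.05, 0.2, seed=4)
        surv["x2"] = rng.normal(size=n)  # independent noise covariate
        fit = th.cox_fit(surv, ["x1", "x2"]).set_index("covariate")
        assert fit.loc["x1", "beta"] == pytest.approx(-0.5, abs=0.2)
        assert abs(fit.loc["x2", "beta"]) < 0.2

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(2)
        x = pd.Series(rng.normal(size=50), index=[f"s{i}" for i in range(50)], name="x")
        surv = th.simulate_survival(x, 0.0, 0.05, 0.0, seed=5)
        surv["x_dup"] = surv["x"] * 2.0
        with pytest.raises(ValueError, match="collinear"):
            th.cox_fit(surv, ["x", "x_dup"])

    def test_zero_events_rejected(self):
        surv = pd.DataFrame(
            {"time": [1.0, 2.0, 3.0], "event": [0, 0, 0], "x": [0.1, 0.2, 0.3]},
            index=["a", "b", "c"],
        )
        with pytest.raises(ValueError, match="events"):
            th.cox_fit(surv, "x")


class TestScreenGenes:
    @staticmethod
    def tables(p_cor_vals, p_cox_vals):
        genes = [f"g{i}" for i in range(len(p_cor_vals))]
        cor = pd.DataFrame(
            {"gene": genes, "pearson_r": 0.5, "p_correlation": p_cor_vals,
             "undefined": False}
        )
        cox = pd.DataFrame(
            {"gene": genes, "beta": -0.1, "hazard_ratio": 0.9,
             "ci_low": 0.8, "ci_high": 1.0, "p_cox": p_cox_vals}
        )
        return cor, cox

    def test_selection_is_conjunction(self):
        cor, cox = self.tables([0.01, 0.2, 0.01], [0.2, 0.01, 0.01])
        out = th.screen_genes(cor, cox).set_index("gene")
        assert bool(out.loc["g0", "tme_associated"]) and not bool(out.loc["g0", "selected"])
        assert bool(out.loc["g1", "survival_associated"]) and not bool(out.loc["g1", "selected"])
        assert bool(out.loc["g2", "selected"])
        assert (out["selected"] == (out["tme_associated"] & out["survival_associated"])).all()

    def test_universe_mismatch_rejected(self):
        cor, cox = self.tables([0.01], [0.01])
        cox = cox.assign(gene=["other"])
        with pytest.raises(ValueError, match="universe"):
            th.screen_genes(cor, cox)

    def test_empty_candidate_list(self):
        cor, cox = self.tables([], [])
        out = th.screen_genes(cor, cox)
        assert len(out) == 0

    def test_bh_adjustment_weakens_marginal_hits(self):
        pvals = [0.04] * 10
        cor, cox = self.tables(pvals, [0.001] * 10)
        plain = th.screen_genes(cor, cox)
        adjusted = th.screen_genes(cor, cox, adjust="fdr_bh")
        assert plain["tme_associated"].all()
        assert adjusted["tme_associated"].sum() <= plain["tme_associated"].sum()


class TestDichotomize:
    def test_median_split(self):
        v = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        labels = th.dichotomize(v)
        assert list(labels) == ["low", "low", "high", "high"]

    def test_odd_n_median_labeled_low(self):
        v = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        assert list(th.dichotomize(v)) == ["low", "low", "high"]

    def test_order_invariant(self):
        v = pd.Series([5.0, 1.0, 3.0, 2.0], index=list("abcd"))
        l1 = th.dichotomize(v)
        l2 = th.dichotomize(v.sort_values())
        assert l1.sort_index().equals(l2.sort_index())

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            th.dichotomize(pd.Series([1.0, 1.0]))


class TestKMLogrank:
    def test_toy_matches_oracle(self, toy_survival):
        surv, groups = toy_survival
        res = th.km_logrank(surv, groups)
        chi2, p = logrank_oracle([1, 2, 3], [1, 1, 1], [4, 5, 6], [1, 1, 1])
        assert res.logrank_chi2 == pytest.approx(chi2, abs=1e-9)
        assert res.logrank_p == pytest.approx(p, abs=1e-9)

    def test_km_without_censoring_is_empirical_survival(self, toy_survival):
        surv, groups = toy_survival
        res = th.km_logrank(surv, groups)
        curve = res.curves["A"].set_index("time")["survival"]
        # times 1,2,3 all events in a group of 3: S = 2/3, 1/3, 0
        assert curve.loc[1.0] == pytest.approx(2 / 3)
        assert curve.loc[2.0] == pytest.approx(1 / 3)
        assert curve.loc[3.0] == pytest.approx(0.0)

    def test_no_events_flagged_undefined(self):
        surv = pd.DataFrame(
            {"time": [1.0, 2.0, 3.0, 4.0], "event": [0, 0, 0, 0]},
            index=list("abcd"),
        )
        groups = pd.Series(["x", "x", "y", "y"], index=surv.index)
        res = th.km_logrank(surv, groups)
        assert not res.logrank_defined
        for curve in res.curves.values():
            assert (curve["survival"] == 1.0).all()

    def test_single_group_rejected(self, toy_survival):
        surv, _ = toy_survival
        one = pd.Series(["A"] * 6, index=surv.index)
        with pytest.raises(ValueError, match="2 groups"):
            th.km_logrank(surv, one)

    def test_survival_curves_non_increasing_from_one(self):
        rng = np.random.default_rng(7)
        x = pd.Series(rng.normal(size=80), index=[f"s{i}" for i in range(80)], name="x")
        surv = th.simulate_survival(x, -0.5, 0.05, 0.3, seed=8)
        res = th.km_logrank(surv, th.dichotomize(x))
        for curve in res.curves.values():
            s = curve["survival"].to_numpy()
            assert s[0] == 1.0 or curve["time"].iloc[0] == 0.0
            assert (np.diff(s) <= 1e-12).all()


class TestCompareGroups:
    def test_identical_groups_statistic_at_null_center(self):
        v = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], index=list("abcdef"))
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=v.index)
        stat, p = th.compare_groups(v, labels)
        assert stat == pytest.approx(4.5)  # n1*n2/2
        assert p > 0.9

    def test_separated_groups_match_exact_enumeration(self):
        a = [float(i) for i in range(1, 9)]
        b = [float(i) for i in range(20, 28)]
        v = pd.Series(a + b, index=[f"s{i}" for i in range(16)])
        labels = pd.Series(["A"] * 8 + ["B"] * 8, index=v.index)
        _, p = th.compare_groups(v, labels)
        assert p < 0.001
        exact = ranksum_exact_p(a, b)
        # asymptotic vs exact agree on order of magnitude at this separation
        assert p == pytest.approx(exact, abs=5e-4) or p < exact

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        v = pd.Series(rng.uniform(1, 2, 20), index=[f"s{i}" for i in range(20)])
        labels = pd.Series(["A"] * 10 + ["B"] * 10, index=v.index)
        assert th.compare_groups(v, labels) == th.compare_groups(np.exp(v) * 3, labels)

    def test_empty_group_rejected(self):
        v = pd.Series([1.0, 2.0], index=["a", "b"])
        labels = pd.Series(["A", "A"], index=v.index)
        with pytest.raises(ValueError):
            th.compare_groups(v, labels)
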