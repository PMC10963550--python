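"""Gene screening against the TME-hot score and survival validation.

The screen mirrors a two-arm selection: a candidate cancer cell-intrinsic
gene is *TME-associated* when its Pearson correlation with the TME-hot score
is significant, *survival-associated* when its univariate Cox coefficient is
significant, and *selected* when both hold (the intersection). Kaplan–Meier
curves with the log-rank test and a rank-sum comparison between responder
groups support downstream validation of individual candidates.

Cox models are proportional-hazards partial-likelihood fits with Efron tie
handling (lifelines); the screen uses continuous expression, dichotomization
being reserved for Kaplan–Meier display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, validate_survival

__all__ = [
    "correlate_with_score",
    "cox_fit",
    "screen_genes",
    "dichotomize",
    "km_logrank",
    "KMResult",
    "compare_groups",
]


def correlate_with_score(
    expr: ExpressionMatrix, score: pd.Series
) -> pd.DataFrame:
    """Two-sided Pearson test of every gene against a per-sample score.

    Constant genes are kept with ``r = NaN`` and ``undefined = True`` rather
    than dropped silently.
    """
    common = expr.units.intersection(score.index)
    if len(common) < 3:
        raise ValueError("need at least 3 samples for a correlation test")
    if not np.isfinite(score.loc[common]).all():
        raise ValueError("score contains non-finite values")
    data = expr.data[common]
    s = score.loc[common].to_numpy(dtype=float)

    rows = []
    for gene, values in data.iterrows():
        x = values.to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(s) == 0:
            rows.append((gene, np.nan, np.nan, True))
            continue
        r, p = stats.pearsonr(x, s)
        rows.append((gene, float(r), float(p), False))
    return pd.DataFrame(
        rows, columns=["gene", "pearson_r", "p_correlation", "undefined"]
    )


def cox_fit(
    survival: pd.DataFrame, covariates: list[str] | str
) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties) for one or more covariates.

    Returns one row per covariate: ``beta, hazard_ratio, ci_low, ci_high,
    p_cox`` (Wald confidence interval and p value).
    """
    validate_survival(survival)
    if isinstance(covariates, str):
        covariates = [covariates]
    if len(covariates) == 0:
        raise ValueError("no covariates given")
    missing = [c for c in covariates if c not in survival.columns]
    if missing:
        raise ValueError(f"covariates absent from survival table: {missing}")
    if survival["event"].sum() == 0:
        raise ValueError("no events observed; the partial likelihood is flat")
    X = survival[covariates].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("covariates contain non-finite values")
    centered = X - X.mean(axis=0)
    if np.linalg.matrix_rank(centered) < len(covariates):
        raise ValueError("covariates are collinear (rank-deficient design)")

    df = survival[["time", "event", *covariates]]
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # convergence failures, separation
        raise RuntimeError(
            f"Cox fit failed for covariates {covariates}: {exc}"
        ) from exc

    summary = fitter.summary
    out = pd.DataFrame(
        {
            "covariate": summary.index,
            "beta": summary["coef"].to_numpy(),
            "hazard_ratio": summary["exp(coef)"].to_numpy(),
            "ci_low": summary["exp(coef) lower 95%"].to_numpy(),
            "ci_high": summary["exp(coef) upper 95%"].to_numpy(),
            "p_cox": summary["p"].to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def screen_genes(
    cor_table: pd.DataFrame,
    cox_table: pd.DataFrame,
    p_cor: float = 0.05,
    p_cox: float = 0.05,
    *,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Combine the correlation and Cox arms into selection flags.

    A gene is ``tme_associated`` when its correlation p value is below
    ``p_cor``, ``survival_associated`` when its Cox p value is below
    ``p_cox``, and ``selected`` when both hold. ``adjust="fdr_bh"`` applies
    Benjamini–Hochberg within each arm before thresholding (off by default:
    the screen is a candidate filter, not a confirmatory test).
    """
    if "gene" not in cox_table.columns:
        cox_table = cox_table.rename(columns={"covariate": "gene"})
    cor_genes = set(cor_table["gene"])
    cox_genes = set(cox_table["gene"])
    if cor_genes != cox_genes:
        raise ValueError(
            "correlation and Cox tables cover different gene universes: "
            f"{sorted(cor_genes ^ cox_genes)[:10]}"
        )
    merged = cor_table.merge(
        cox_table[["gene", "beta", "hazard_ratio", "ci_low", "ci_high", "p_cox"]],
        on="gene",
        how="inner",
    )
    if merged.empty:
        return merged.assign(tme_associated=[], survival_associated=[], selected=[])

    pc = merged["p_correlation"].to_numpy(dtype=float)
    px = merged["p_cox"].to_numpy(dtype=float)
    if adjust is not None:
        ok = np.isfinite(pc)
        pc = pc.copy()
        pc[ok] = multipletests(pc[ok], method=adjust)[1]
        px = multipletests(px, method=adjust)[1]
    merged["tme_associated"] = np.where(np.isfinite(pc), pc < p_cor, False)
    merged["survival_associated"] = px < p_cox
    merged["selected"] = merged["tme_associated"] & merged["survival_associated"]
    return merged


def dichotomize(values: pd.Series, method: str = "median", q: float = 0.5) -> pd.Series:
    """Split a continuous vector into ``low``/``high`` groups.

    ``high`` means strictly above the cutpoint (the median by default, a
    quantile with ``method="quantile"``); with an odd sample count the median
    element is labeled ``low``.
    """
    x = values.astype(float)
    if x.nunique() < 2:
        raise ValueError("cannot dichotomize a constant vector")
    if method == "median":
        cut = float(x.median())
    elif method == "quantile":
        cut = float(x.quantile(q))
    else:
        raise ValueError("method must be 'median' or 'quantile'")
    labels = pd.Series(
        np.where(x > cut, "high", "low"), index=x.index, name="group"
    )
    return labels


@dataclass
class KMResult:
    """Kaplan–Meier curves per group plus the log-rank comparison."""

    curves: dict[str, pd.DataFrame]  # per group: time, survival, at_risk
    logrank_chi2: float
    logrank_p: float
    logrank_defined: bool


def km_logrank(survival: pd.DataFrame, groups: pd.Series) -> KMResult:
    """Product-limit survival curves per group and the log-rank test.

    With a single group the curves are computable but the comparison is not,
    so the call fails; with no events in any group the curves are flat and
    the test statistic is flagged undefined rather than fabricated.
    """
    validate_survival(survival)
    groups = groups.loc[survival.index]
    labels = groups.unique().tolist()
    if len(labels) < 2:
        raise ValueError("log-rank test requires at least 2 groups")

    curves: dict[str, pd.DataFrame] = {}
    for label in labels:
        mask = groups == label
        if mask.sum() == 0:
            raise ValueError(f"group {label!r} is empty")
        km = KaplanMeierFitter()
        km.fit(survival.loc[mask, "time"], survival.loc[mask, "event"])
        table = km.event_table
        curves[str(label)] = pd.DataFrame(
            {
                "time": km.survival_function_.index.to_numpy(),
                "survival": km.survival_function_.iloc[:, 0].to_numpy(),
                "at_risk": table["at_risk"].reindex(
                    km.survival_function_.index, method="ffill"
                ).to_numpy(),
            }
        )

    if survival["event"].sum() == 0:
        return KMResult(curves, np.nan, np.nan, False)
    res = multivariate_logrank_test(
        survival["time"], groups, survival["event"]
    )
    return KMResult(
        curves, float(res.test_statistic), float(res.p_value), True
    )


def compare_groups(values: pd.Series, labels: pd.Series) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of a quantity between 2 groups."""
    labels = labels.loc[values.index]
    names = labels.unique().tolist()
    if len(names) != 2:
        raise ValueError("compare_groups requires exactly 2 groups")
    a = values[labels == names[0]].to_numpy(dtype=float)
    b = values[labels == names[1]].to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(stat), float(p)
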