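"""Synthetic data with known ground truth.

Three generators cover the inputs the pipeline consumes:

* :func:`simulate_cell_atlas` — a clustered single-cell count matrix with
  planted per-cluster marker genes (negative-binomial counts, a fold-change
  multiplier on each cluster's markers inside that cluster only);
* :func:`simulate_bulk_cohort` — bulk samples formed as convex mixtures of
  "hot" and "cold" cell-population mean profiles with a known per-sample hot
  fraction, plus one planted cancer-intrinsic gene tracking the hot fraction
  and optional null decoy genes;
* :func:`simulate_survival` — exponential event times whose hazard depends
  log-linearly on a covariate, with independent exponential censoring
  calibrated to a target censored proportion.

All generators are pure functions of their parameters and an explicit seed.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datatypes import ExpressionMatrix, SimTruth

__all__ = [
    "DEFAULT_CLUSTER_LINEAGE",
    "DEFAULT_HOT_CLUSTERS",
    "simulate_cell_atlas",
    "simulate_bulk_cohort",
    "simulate_survival",
    "mean_profiles",
]

# Default atlas grid: the immune-cell cluster landscape the scoring module
# expects (12 T/NK clusters, 9 myeloid clusters) plus a cancer-cell cluster.
DEFAULT_CLUSTER_LINEAGE: dict[str, str] = {
    "Tn_LEF1": "T",
    "CD4_Tcm_LMNA": "T",
    "CD4_Tem_IL7R": "T",
    "CD4_Trg_FOXP3": "T",
    "CD4_Ttr_CXCL13": "T",
    "CD8_Ttr_CXCL13": "T",
    "CD8_Tem_GZMK": "T",
    "CD8_Teff_GZMB": "T",
    "Tact_IFI6": "T",
    "Tprf_MKI67": "T",
    "NK_GNLY": "NK",
    "NK_FCGR3A": "NK",
    "TAM_SPP1/TREM2": "myeloid",
    "TAM_FOLR2": "myeloid",
    "TAM_CXCL9": "myeloid",
    "Mono": "myeloid",
    "pDC": "myeloid",
    "cDC1": "myeloid",
    "cDC2": "myeloid",
    "cDC3": "myeloid",
    "Cycling_myeloid": "myeloid",
    "Cancer": "cancer",
}

# Immunologically "hot" populations: effector/tumor-reactive/activated T
# cells, NK cells, the anti-tumor TAM subset and cross-presenting cDC1.
DEFAULT_HOT_CLUSTERS: tuple[str, ...] = (
    "CD4_Ttr_CXCL13",
    "CD8_Ttr_CXCL13",
    "CD8_Teff_GZMB",
    "Tact_IFI6",
    "NK_GNLY",
    "NK_FCGR3A",
    "TAM_CXCL9",
    "cDC1",
)

#: Minimum baseline mean (counts/cell) for a gene to be eligible as a planted
#: marker: a marker gene must be detectably expressed for a fold change to be
#: biologically meaningful.
_MARKER_MIN_BASELINE = 0.5


def simulate_cell_atlas(
    n_clusters: int | Mapping[str, str],
    cells_per_cluster: int,
    n_genes: int,
    markers_per_cluster: int,
    marker_fold: float,
    seed: int,
    *,
    dispersion: float = 0.5,
    baseline_sdlog: float = 0.5,
) -> tuple[ExpressionMatrix, pd.DataFrame, SimTruth]:
    """Simulate a clustered single-cell count matrix with planted markers.

    Parameters
    ----------
    n_clusters
        Either a cluster count (clusters get generic names and lineage
        ``"other"``) or a mapping ``cluster name -> lineage label`` such as
        :data:`DEFAULT_CLUSTER_LINEAGE`.
    cells_per_cluster, n_genes, markers_per_cluster
        Sizes; markers are disjoint across clusters, so
        ``markers_per_cluster * n_clusters`` may not exceed ``n_genes``.
    marker_fold
        Multiplier (> 1) applied to each planted marker's mean inside its own
        cluster only.
    dispersion
        Negative-binomial dispersion (variance = mu + dispersion * mu^2).
    baseline_sdlog
        Log-scale s.d. of the log-normal baseline gene means (median 1
        count/cell).

    Returns
    -------
    (ExpressionMatrix raw counts, annotation DataFrame, SimTruth)
    """
    if isinstance(n_clusters, Mapping):
        cluster_lineage = dict(n_clusters)
    else:
        cluster_lineage = {f"cluster_{i + 1}": "other" for i in range(int(n_clusters))}
    k = len(cluster_lineage)
    if k < 2:
        raise ValueError("need at least 2 clusters")
    if cells_per_cluster <= 0:
        raise ValueError("cells_per_cluster must be positive")
    if n_genes <= 0 or markers_per_cluster <= 0:
        raise ValueError("n_genes and markers_per_cluster must be positive")
    if marker_fold <= 1:
        raise ValueError("marker_fold must exceed 1")
    if markers_per_cluster * k > n_genes:
        raise ValueError(
            f"cannot plant {markers_per_cluster} disjoint markers in each of "
            f"{k} clusters with only {n_genes} genes"
        )

    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    baseline = np.exp(rng.normal(0.0, baseline_sdlog, size=n_genes))

    eligible = np.flatnonzero(baseline >= _MARKER_MIN_BASELINE)
    if len(eligible) < markers_per_cluster * k:
        eligible = np.argsort(baseline)[::-1][: markers_per_cluster * k]
    chosen = rng.choice(eligible, size=markers_per_cluster * k, replace=False)

    clusters = list(cluster_lineage)
    planted: dict[str, list[str]] = {}
    n_cells = cells_per_cluster * k
    mu = np.tile(baseline[:, None], (1, n_cells)).astype(float)
    cluster_of_cell = np.repeat(np.arange(k), cells_per_cluster)
    for ci, cl in enumerate(clusters):
        idx = chosen[ci * markers_per_cluster : (ci + 1) * markers_per_cluster]
        planted[cl] = [genes[g] for g in sorted(idx)]
        cols = np.flatnonzero(cluster_of_cell == ci)
        mu[np.ix_(idx, cols)] *= marker_fold

    # NB(mean mu, var mu + dispersion*mu^2): size r = 1/dispersion.
    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    cells = [f"cell_{i + 1:05d}" for i in range(n_cells)]
    expr = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=cells), lognorm=False
    )
    ann = pd.DataFrame(
        {
            "cluster": [clusters[c] for c in cluster_of_cell],
            "lineage": [cluster_lineage[clusters[c]] for c in cluster_of_cell],
        },
        index=pd.Index(cells, name="cell"),
    )
    truth = SimTruth(seed=seed, planted_markers=planted)
    return expr, ann, truth


def mean_profiles(expr: ExpressionMatrix, ann: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster mean expression profiles (genes x clusters)."""
    missing = ann.index.difference(expr.units)
    if len(missing):
        raise ValueError(f"annotated cells absent from matrix: {list(missing)[:5]}")
    groups = ann["cluster"]
    return expr.data[ann.index].T.groupby(groups).mean().T


def simulate_bulk_cohort(
    atlas_profiles: pd.DataFrame,
    hot_clusters: Sequence[str],
    n_samples: int,
    noise_sd: float,
    tme_gene_slope: float,
    seed: int,
    *,
    n_decoys: int = 0,
    planted_gene: str = "CI_PLANTED",
    planted_baseline: float = 1.0,
    hot_fraction: Sequence[float] | None = None,
) -> tuple[ExpressionMatrix, SimTruth]:
    """Simulate bulk samples as hot/cold mixtures with known hot fractions.

    Each sample draws a hot fraction f ~ Uniform(0, 1) (unless ``hot_fraction``
    pins it) and its profile is ``f * mean(hot cluster profiles) +
    (1 - f) * mean(cold cluster profiles)`` plus Gaussian noise truncated at
    zero. One cancer-intrinsic gene is appended with mean
    ``planted_baseline + tme_gene_slope * f``, together with ``n_decoys`` null
    candidate genes whose means are independent of f.
    """
    all_clusters = list(atlas_profiles.columns)
    hot = [c for c in all_clusters if c in set(hot_clusters)]
    if len(hot) == 0:
        raise ValueError("hot_clusters is empty or disjoint from atlas clusters")
    if len(hot) == len(all_clusters):
        raise ValueError("hot_clusters must be a strict subset of clusters")
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    rng = np.random.default_rng(seed)
    if hot_fraction is None:
        f = rng.uniform(0.0, 1.0, size=n_samples)
    else:
        f = np.asarray(hot_fraction, dtype=float)
        if f.shape != (n_samples,):
            raise ValueError("hot_fraction length must equal n_samples")
        if ((f < 0) | (f > 1)).any():
            raise ValueError("hot_fraction outside [0, 1]")

    cold = [c for c in all_clusters if c not in set(hot)]
    hot_profile = atlas_profiles[hot].mean(axis=1).to_numpy()
    cold_profile = atlas_profiles[cold].mean(axis=1).to_numpy()

    mix = np.outer(hot_profile, f) + np.outer(cold_profile, 1.0 - f)
    if noise_sd > 0:
        mix = mix + rng.normal(0.0, noise_sd, size=mix.shape)
    mix = np.clip(mix, 0.0, None)

    samples = [f"sample_{i + 1:03d}" for i in range(n_samples)]
    rows = list(atlas_profiles.index)
    planted_vals = planted_baseline + tme_gene_slope * f
    if noise_sd > 0:
        planted_vals = planted_vals + rng.normal(0.0, noise_sd, size=n_samples)
    blocks = [mix, np.clip(planted_vals, 0.0, None)[None, :]]
    rows = rows + [planted_gene]
    if n_decoys > 0:
        decoy_base = rng.uniform(0.5, 2.0, size=n_decoys)
        decoys = np.tile(decoy_base[:, None], (1, n_samples))
        if noise_sd > 0:
            decoys = decoys + rng.normal(0.0, noise_sd, size=decoys.shape)
        blocks.append(np.clip(decoys, 0.0, None))
        rows = rows + [f"DECOY_{i + 1:03d}" for i in range(n_decoys)]

    bulk = ExpressionMatrix(
        pd.DataFrame(np.vstack(blocks), index=rows, columns=samples), lognorm=True
    )
    truth = SimTruth(
        seed=seed,
        hot_fraction=pd.Series(f, index=samples, name="hot_fraction"),
        planted_tme_gene=(planted_gene, float(tme_gene_slope)),
    )
    return bulk, truth


def simulate_survival(
    covariate_values: pd.Series,
    log_hr: float,
    baseline_rate: float,
    censor_rate: float,
    seed: int,
) -> pd.DataFrame:
    """Simulate right-censored survival with a log-linear hazard.

    Event times are exponential with per-subject hazard
    ``baseline_rate * exp(log_hr * x)``; censoring times are independent
    exponential with rate calibrated so the expected censored proportion
    equals ``censor_rate``. Returns a survival table (index = subject,
    columns ``time``, ``event`` and the covariate).
    """
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must lie in [0, 1)")
    x = np.asarray(covariate_values, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("covariate values must be finite")

    rng = np.random.default_rng(seed)
    rate = baseline_rate * np.exp(log_hr * x)
    t_event = rng.exponential(1.0 / rate)

    name = covariate_values.name or "x"
    index = covariate_values.index

    if censor_rate == 0:
        time, event = t_event, np.ones(len(x), dtype=int)
    else:
        # P(censored | rate_i) = c / (c + rate_i); solve mean over subjects.
        def expected_censored(log_c: float) -> float:
            c = np.exp(log_c)
            return float(np.mean(c / (c + rate))) - censor_rate

        log_c = brentq(expected_censored, -30.0, 30.0)
        t_cens = rng.exponential(np.exp(-log_c), size=len(x))
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)

    return pd.DataFrame({"time": time, "event": event, name: x}, index=index)
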