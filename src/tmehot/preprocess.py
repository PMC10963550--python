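"""Cell quality control, normalization, and per-cluster marker detection.

QC retains cells with 200–7000 detected genes (inclusive) and at most 15%
mitochondrial counts. Marker detection is a one-vs-rest two-sided Wilcoxon
rank-sum test per (cluster, gene) on log-normalized data, with Seurat-style
detection-fraction and fold-change pre-filters and Bonferroni correction
within each cluster.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, validate_annotation

__all__ = ["qc_filter", "lognormalize", "find_markers", "top_markers"]

#: QC bounds: detected-gene count within [min, max], mito fraction <= cap.
QC_MIN_GENES = 200
QC_MAX_GENES = 7000
QC_MAX_MITO_FRACTION = 0.15


def qc_filter(
    counts: ExpressionMatrix,
    mito_genes: Sequence[str],
    *,
    min_genes: int = QC_MIN_GENES,
    max_genes: int = QC_MAX_GENES,
    max_mito_fraction: float = QC_MAX_MITO_FRACTION,
) -> ExpressionMatrix:
    """Drop low-quality cells; never alters retained values or the gene set.

    A cell passes when its detected-gene count lies in
    ``[min_genes, max_genes]`` (bounds inclusive) and its mitochondrial count
    fraction is at most ``max_mito_fraction`` (boundary retained).
    """
    if counts.lognorm:
        raise ValueError("qc_filter expects raw counts")
    if counts.data.shape[1] == 0:
        raise ValueError("expression matrix has no cells")
    data = counts.data
    unknown = [g for g in mito_genes if g not in data.index]
    if unknown:
        raise ValueError(f"mito genes absent from matrix: {unknown}")

    detected = (data > 0).sum(axis=0)
    totals = data.sum(axis=0)
    mito = data.loc[list(mito_genes)].sum(axis=0) if len(mito_genes) else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito / totals, 1.0)

    keep = (
        (detected >= min_genes)
        & (detected <= max_genes)
        & (mito_frac <= max_mito_fraction)
    )
    if not keep.any():
        warnings.warn("qc_filter removed every cell", UserWarning, stacklevel=2)
    return ExpressionMatrix(data.loc[:, keep].copy(), lognorm=False)


def lognormalize(counts: ExpressionMatrix, scale_total: float = 1e4) -> ExpressionMatrix:
    """Library-size normalize each cell to ``scale_total`` then log1p."""
    if counts.lognorm:
        raise ValueError("matrix is already log-normalized")
    totals = counts.data.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"cells with zero total counts: {zero}")
    norm = np.log1p(counts.data / totals * scale_total)
    return ExpressionMatrix(norm, lognorm=True)


def find_markers(
    expr: ExpressionMatrix,
    ann: pd.DataFrame,
    *,
    group_col: str = "cluster",
    min_frac: float = 0.1,
    min_log2fc: float = 0.25,
    only_pos: bool = True,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum markers per cluster.

    For each cluster, genes detected in at least ``min_frac`` of either the
    in-group or the out-group and with
    ``log2(mean(expm1 in) + 1) - log2(mean(expm1 out) + 1) >= min_log2fc``
    are tested with a two-sided rank-sum test; p values are
    Bonferroni-adjusted over the genes tested within that cluster.

    Set ``group_col="lineage"`` to compute cell-type-level markers.

    Returns a MarkerTable: columns ``cluster, gene, log2_fold_change,
    frac_expr_in, frac_expr_out, p_value, p_adjusted``.
    """
    if not expr.lognorm:
        raise ValueError("find_markers expects log-normalized data")
    validate_annotation(ann)
    unknown = ann.index.difference(expr.units)
    if len(unknown):
        raise ValueError(f"annotated cells absent from matrix: {list(unknown)[:5]}")

    groups = ann[group_col]
    sizes = groups.value_counts()
    small = sizes.index[sizes < 2].tolist()
    if small:
        raise ValueError(f"clusters with fewer than 2 cells: {small}")

    mat = expr.data[ann.index]
    vals = mat.to_numpy()
    expm1 = np.expm1(vals)
    detected = vals > 0
    genes = mat.index.to_numpy()

    rows: list[pd.DataFrame] = []
    for cluster in sizes.sort_index().index:
        in_mask = (groups == cluster).to_numpy()
        x_in = vals[:, in_mask]
        x_out = vals[:, ~in_mask]

        frac_in = detected[:, in_mask].mean(axis=1)
        frac_out = detected[:, ~in_mask].mean(axis=1)
        mean_in = expm1[:, in_mask].mean(axis=1)
        mean_out = expm1[:, ~in_mask].mean(axis=1)
        log2fc = np.log2(mean_in + 1.0) - np.log2(mean_out + 1.0)

        test = np.maximum(frac_in, frac_out) >= min_frac
        test &= log2fc >= min_log2fc if only_pos else np.abs(log2fc) >= min_log2fc
        if not test.any():
            continue

        res = stats.mannwhitneyu(
            x_in[test].T, x_out[test].T, alternative="two-sided", method="asymptotic"
        )
        n_tested = int(test.sum())
        padj = np.minimum(res.pvalue * n_tested, 1.0)
        rows.append(
            pd.DataFrame(
                {
                    "cluster": cluster,
                    "gene": genes[test],
                    "log2_fold_change": log2fc[test],
                    "frac_expr_in": frac_in[test],
                    "frac_expr_out": frac_out[test],
                    "p_value": res.pvalue,
                    "p_adjusted": padj,
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "cluster",
                "gene",
                "log2_fold_change",
                "frac_expr_in",
                "frac_expr_out",
                "p_value",
                "p_adjusted",
            ]
        )
    return pd.concat(rows, ignore_index=True)


def top_markers(mt: pd.DataFrame, cluster: str, n: int) -> list[str]:
    """Up to ``n`` genes of a cluster ranked by descending fold change.

    Ties break by ascending p value, then lexicographic gene id.
    """
    sub = mt[mt["cluster"] == cluster]
    if sub.empty:
        raise KeyError(f"cluster {cluster!r} not present in marker table")
    ordered = sub.sort_values(
        ["log2_fold_change", "p_value", "gene"], ascending=[False, True, True]
    )
    return ordered["gene"].head(n).tolist()
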