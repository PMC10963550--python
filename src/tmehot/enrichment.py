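"""Single-sample gene set enrichment (ssGSEA).

For one sample, genes are ranked 1..N by expression (N = highest, average
ranks on ties). Walking the genes in decreasing rank order, the enrichment
score of a gene set S is the summed difference between the
rank-power-weighted ECDF of the in-set genes and the unweighted ECDF of the
out-of-set genes:

    ES = sum_i [ P_in(i) - P_out(i) ]
    P_in(i)  = sum_{j<=i, j in S} r_j^alpha / sum_{j in S} r_j^alpha
    P_out(i) = #{j<=i, j not in S} / (N - |S|)

with alpha = 0.25 by default. Because the statistic depends on expression
only through ranks, it is invariant to any strictly increasing per-sample
transform. Matrix-level normalization divides every score by the
(max - min) range of the whole matrix.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import EnrichmentMatrix, ExpressionMatrix, SignatureSet

__all__ = ["rank_genes", "ssgsea_es", "ssgsea_matrix"]

logger = logging.getLogger(__name__)


def rank_genes(expr_column: pd.Series | np.ndarray) -> pd.Series:
    """Ranks 1..N with N for the highest expression; ties get average rank."""
    values = np.asarray(expr_column, dtype=float)
    if values.size == 0:
        raise ValueError("cannot rank an empty expression vector")
    if not np.isfinite(values).all():
        raise ValueError("expression vector contains non-finite values")
    ranks = rankdata(values, method="average")
    index = expr_column.index if isinstance(expr_column, pd.Series) else None
    return pd.Series(ranks, index=index)


def _es_from_ranks(ranks: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    # Stable sort on descending rank: ties keep input gene order.
    order = np.argsort(-ranks, kind="stable")
    in_ordered = in_set[order]
    n = ranks.size
    n_in = int(in_set.sum())

    weights = np.where(in_ordered, np.abs(ranks[order]) ** alpha, 0.0)
    p_in = np.cumsum(weights) / weights.sum()
    p_out = np.cumsum(~in_ordered) / (n - n_in)
    return float(np.sum(p_in - p_out))


def ssgsea_es(ranks: pd.Series, gene_set: Sequence[str], alpha: float = 0.25) -> float:
    """Enrichment score of one gene set in one ranked sample."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    members = set(gene_set)
    in_set = ranks.index.isin(members)
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError("gene set has no overlap with the gene universe")
    if n_in == len(ranks):
        raise ValueError(
            "gene set covers the whole universe; out-of-set ECDF is undefined"
        )
    return _es_from_ranks(ranks.to_numpy(dtype=float), in_set, alpha)


def ssgsea_matrix(
    expr: ExpressionMatrix,
    sigs: SignatureSet,
    alpha: float = 0.25,
    normalize: bool = True,
    *,
    on_missing: str = "error",
    max_missing_fraction: float = 0.5,
) -> EnrichmentMatrix:
    """ssGSEA scores for every (signature, sample) pair.

    Genes of a set absent from the matrix are ignored (count logged); a set
    missing more than ``max_missing_fraction`` of its genes, or all of them,
    is an error (``on_missing="drop"`` downgrades this to a warning and
    drops the set).
    """
    if on_missing not in ("error", "drop"):
        raise ValueError("on_missing must be 'error' or 'drop'")
    universe = expr.genes
    usable: dict[str, list[str]] = {}
    bad: list[str] = []
    for name, genes in sigs.items():
        present = [g for g in genes if g in universe]
        n_missing = len(genes) - len(present)
        if n_missing:
            logger.info("signature %s: %d/%d genes absent", name, n_missing, len(genes))
        if len(present) == len(universe):
            raise ValueError(f"signature {name!r} covers the whole gene universe")
        if len(present) == 0 or n_missing > max_missing_fraction * len(genes):
            bad.append(name)
        else:
            usable[name] = present
    if bad:
        if on_missing == "error" or not usable:
            raise ValueError(
                f"signatures with insufficient overlap with the matrix: {bad}"
            )
        logger.warning("dropping signatures with insufficient overlap: %s", bad)

    values = expr.data.to_numpy(dtype=float)
    masks = {
        name: universe.isin(set(genes)).astype(bool) for name, genes in usable.items()
    }
    out = np.empty((len(usable), expr.shape[1]))
    for j in range(expr.shape[1]):
        ranks = rankdata(values[:, j], method="average")
        for i, name in enumerate(usable):
            out[i, j] = _es_from_ranks(ranks, masks[name], alpha)

    scores = pd.DataFrame(out, index=list(usable), columns=expr.units)
    if normalize:
        spread = float(out.max() - out.min())
        if spread == 0:
            raise ValueError("cannot normalize a constant enrichment matrix")
        scores = scores / spread
    return EnrichmentMatrix(scores, alpha=alpha, normalized=normalize)
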