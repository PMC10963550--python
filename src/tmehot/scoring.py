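"""Composite tumor-microenvironment scores built from enrichment scores.

* **TAM score** — ratio of the anti-tumor ``TAM_CXCL9`` enrichment score to
  the pro-tumor ``TAM_SPP1/TREM2`` score. Because normalized enrichment
  scores may be zero or negative, both rows are first min-max rescaled across
  samples to [epsilon, 1] so the ratio is finite, positive and
  rank-preserving.
* **T score** — sum of the ``CD8_Ttr_CXCL13``, ``CD8_Teff_GZMB`` and
  ``Tact_IFI6`` cluster enrichment scores.
* **TME-hot score** — TAM score + T score + NK enrichment + cDC1 enrichment;
  high values indicate an immunologically "hot" tumor.

All components are computed from the same enrichment matrix (a single
normalization pass) so scores are comparable across samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import CompositeScores, EnrichmentMatrix

__all__ = ["rescale_positive", "tam_score", "t_score", "tme_hot_score"]

TAM_NUMERATOR = "TAM_CXCL9"
TAM_DENOMINATOR = "TAM_SPP1/TREM2"
T_SCORE_COMPONENTS = ("CD8_Ttr_CXCL13", "CD8_Teff_GZMB", "Tact_IFI6")
NK_CELLTYPE_ROW = "NK"
NK_CLUSTER_ROWS = ("NK_GNLY", "NK_FCGR3A")
CDC1_ROW = "cDC1"


def rescale_positive(es_row: pd.Series, epsilon: float = 0.01) -> pd.Series:
    """Min-max rescale a row across samples to [epsilon, 1]."""
    x = es_row.astype(float)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise ValueError(
            f"row {es_row.name!r} is constant across samples; "
            "a ratio of constant scores carries no information"
        )
    return (x - lo) / (hi - lo) * (1.0 - epsilon) + epsilon


def tam_score(
    em: EnrichmentMatrix, *, rescale: bool = True, epsilon: float = 0.5
) -> pd.Series:
    """Ratio of the TAM_CXCL9 score to the TAM_SPP1/TREM2 score, per sample.

    The default ``epsilon`` of 0.5 maps both rows to [0.5, 1], bounding the
    ratio in [0.5, 2] symmetrically around 1 on the log scale. A smaller
    epsilon lets the ratio blow up as the denominator approaches its
    floor (the sample with the lowest pro-tumor TAM score), producing a
    heavy-tailed statistic whose variance swamps the other TME-hot terms;
    with the default the four composite components stay on comparable
    scales. ``rescale=False`` skips the rescaling for data already strictly
    positive.
    """
    num = em.row(TAM_NUMERATOR)
    den = em.row(TAM_DENOMINATOR)
    if rescale:
        num, den = rescale_positive(num, epsilon), rescale_positive(den, epsilon)
    elif (den <= 0).any():
        raise ValueError("denominator row has non-positive entries; enable rescale")
    out = num / den
    out.name = "tam_score"
    return out


def t_score(em: EnrichmentMatrix) -> pd.Series:
    """Sum of the three effector/tumor-reactive/activated T-cluster scores."""
    out = sum(em.row(name) for name in T_SCORE_COMPONENTS)
    out.name = "t_score"
    return out


def tme_hot_score(
    em: EnrichmentMatrix,
    *,
    nk_mode: str = "celltype",
    rescale_tam: bool = True,
) -> CompositeScores:
    """TME-hot composite: TAM score + T score + NK ES + cDC1 ES.

    ``nk_mode="celltype"`` (default) reads the NK term from the
    cell-type-level ``NK`` signature row; ``"cluster_sum"`` sums the two NK
    cluster rows instead.

    The TAM term uses the bounded ratio (see :func:`tam_score`): the four
    components are summed unweighted, so each must live on a comparable
    scale for the composite to reflect all of them.
    """
    if nk_mode not in ("celltype", "cluster_sum"):
        raise ValueError("nk_mode must be 'celltype' or 'cluster_sum'")
    tam = tam_score(em, rescale=rescale_tam)
    t = t_score(em)
    if nk_mode == "celltype":
        nk = em.row(NK_CELLTYPE_ROW)
        nk_rows = [NK_CELLTYPE_ROW]
    else:
        nk = sum(em.row(r) for r in NK_CLUSTER_ROWS)
        nk_rows = list(NK_CLUSTER_ROWS)
    cdc1 = em.row(CDC1_ROW)

    table = pd.DataFrame(
        {
            "tam_score": tam,
            "t_score": t,
            "tme_hot": tam + t + nk + cdc1,
        }
    )
    if not np.isfinite(table.to_numpy()).all():
        raise ValueError("composite scores contain non-finite values")
    provenance = {
        "tam_score": [TAM_NUMERATOR, TAM_DENOMINATOR],
        "t_score": list(T_SCORE_COMPONENTS),
        "nk": nk_rows,
        "cdc1": [CDC1_ROW],
    }
    return CompositeScores(table=table, provenance=provenance)
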