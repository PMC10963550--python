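"""Cell-type signature curation from per-cluster marker lists.

Signatures start as each cluster's top-15 markers; genes shared across
related clusters are then removed so that each signature captures what is
specific to its cluster:

* **T-cluster rule** — "general T" genes (top-10 markers of the T lineage as
  a whole) that occur in both the Treg cluster list and at least one other
  T-cluster list are removed (by default from every T-cluster list; a
  Treg-only variant is available since the removal target is ambiguous).
* **TAM rule** — "general myeloid" genes occurring in more than two of the
  TAM cluster lists are removed from the TAM lists.
* **cDC rule** — genes present in all three cDC cluster lists are deleted
  from all three (the rule is defined for exactly three cDC clusters).

Lists for clusters outside these three groups pass through unchanged.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .datatypes import SignatureSet
from .preprocess import top_markers

__all__ = ["general_genes", "curate_signatures"]


def general_genes(mt: pd.DataFrame, lineage_cluster: str, n: int = 10) -> list[str]:
    """Top-``n`` markers of a lineage-level group (e.g. all T cells).

    Used to define the "general T" and "general myeloid" gene lists that the
    curation rules test against.
    """
    return top_markers(mt, lineage_cluster, n)


def curate_signatures(
    top15: Mapping[str, Sequence[str]],
    general_T: Sequence[str],
    general_myeloid: Sequence[str],
    lineage_map: Mapping[str, str],
    treg_cluster: str,
    tam_clusters: Sequence[str],
    cdc_clusters: Sequence[str],
    *,
    t_rule_scope: str = "all",
    allow_empty: bool = False,
) -> tuple[SignatureSet, pd.DataFrame]:
    """Apply the three cross-cluster removal rules to top-15 marker lists.

    Parameters
    ----------
    top15
        Mapping cluster -> ordered marker gene list (each list is the input
        signature; curation only ever removes genes).
    lineage_map
        Mapping cluster -> lineage label; clusters with lineage ``"T"`` are
        subject to the T-cluster rule.
    t_rule_scope
        ``"all"`` removes a flagged general-T gene from every T-cluster list;
        ``"treg_only"`` removes it from the Treg list only.
    allow_empty
        If False (default), a list that empties under curation raises,
        because an empty gene set makes enrichment scoring undefined.

    Returns
    -------
    (SignatureSet, curation report)
        The report has one row per removal: ``gene, rule, clusters``.
    """
    if t_rule_scope not in ("all", "treg_only"):
        raise ValueError("t_rule_scope must be 'all' or 'treg_only'")
    if len(cdc_clusters) != 3:
        raise ValueError("the cDC rule is defined for exactly 3 cDC clusters")
    if len(tam_clusters) == 0:
        raise ValueError("tam_clusters must be non-empty")
    missing = [c for c in (treg_cluster, *tam_clusters, *cdc_clusters) if c not in top15]
    if missing:
        raise ValueError(f"clusters absent from top15 lists: {missing}")
    t_clusters = [c for c in top15 if lineage_map.get(c) == "T"]
    if treg_cluster not in t_clusters:
        raise ValueError(f"treg_cluster {treg_cluster!r} is not a T-lineage cluster")

    curated = {c: list(genes) for c, genes in top15.items()}
    report_rows: list[dict] = []

    def drop(gene: str, rule: str, clusters: Sequence[str]) -> None:
        affected = []
        for c in clusters:
            if gene in curated[c]:
                curated[c].remove(gene)
                affected.append(c)
        if affected:
            report_rows.append(
                {"gene": gene, "rule": rule, "clusters": ",".join(affected)}
            )

    # T-cluster rule: general-T genes in both the Treg list and >= 1 other
    # T-cluster list.
    other_t = [c for c in t_clusters if c != treg_cluster]
    for gene in general_T:
        in_treg = gene in curated[treg_cluster]
        in_other = any(gene in curated[c] for c in other_t)
        if in_treg and in_other:
            target = t_clusters if t_rule_scope == "all" else [treg_cluster]
            drop(gene, "general_T_in_treg_and_other", target)

    # TAM rule: general-myeloid genes in more than two TAM lists.
    for gene in general_myeloid:
        occur = [c for c in tam_clusters if gene in curated[c]]
        if len(occur) > 2:
            drop(gene, "general_myeloid_in_gt2_TAM", occur)

    # cDC rule: genes present in all 3 cDC lists.
    shared = set(curated[cdc_clusters[0]])
    for c in cdc_clusters[1:]:
        shared &= set(curated[c])
    for gene in sorted(shared):
        drop(gene, "in_all_3_cDC", list(cdc_clusters))

    emptied = [c for c, genes in curated.items() if len(genes) == 0]
    if emptied and not allow_empty:
        raise ValueError(
            f"curation emptied signature lists for clusters {emptied}; "
            "an empty gene set makes enrichment scoring undefined"
        )
    for c in emptied:
        del curated[c]

    lineage_tag = {}
    for c in curated:
        if c in set(tam_clusters):
            lineage_tag[c] = "TAM-cluster"
        elif c in set(cdc_clusters):
            lineage_tag[c] = "cDC-cluster"
        elif c in t_clusters:
            lineage_tag[c] = "T-cluster"
        else:
            lineage_tag[c] = lineage_map.get(c, "other")

    report = pd.DataFrame(report_rows, columns=["gene", "rule", "clusters"])
    return SignatureSet(curated, lineage_tag), report
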