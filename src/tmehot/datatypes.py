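"""Shared containers for the pipeline.

Conventions
-----------
* Expression matrices are genes-in-rows pandas DataFrames (columns are
  cells for single-cell data, samples for bulk data).
* Cell annotations are DataFrames indexed by cell id with ``cluster`` and
  ``lineage`` columns.
* Survival tables are DataFrames indexed by sample id with ``time`` (months,
  strictly positive) and ``event`` (0/1) columns plus optional covariates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SignatureSet",
    "EnrichmentMatrix",
    "CompositeScores",
    "SimTruth",
    "validate_annotation",
    "validate_survival",
]


@dataclass
class ExpressionMatrix:
    """Genes x units (cells or samples) matrix of non-negative finite values.

    ``lognorm`` distinguishes log-normalized data from raw counts; operations
    that require one or the other check the flag and refuse the wrong input.
    """

    data: pd.DataFrame
    lognorm: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.shape[0] == 0:
            raise ValueError("expression matrix has no genes")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate unit identifiers: {dups}")
        vals = self.data.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("expression matrix contains non-finite values")
        if (vals < 0).any():
            raise ValueError("expression matrix contains negative values")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def units(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(self.data.loc[list(genes)].copy(), lognorm=self.lognorm)


class SignatureSet:
    """Named gene lists plus a lineage tag per signature.

    Lineage tags classify each set for downstream curation/scoring
    (e.g. ``"T-cluster"``, ``"TAM-cluster"``, ``"cDC-cluster"``,
    ``"cell-type"``, ``"other"``).
    """

    def __init__(
        self,
        sets: Mapping[str, Sequence[str]],
        lineage: Mapping[str, str] | None = None,
    ) -> None:
        self.sets: dict[str, list[str]] = {}
        for name, genes in sets.items():
            genes = list(genes)
            if len(genes) == 0:
                raise ValueError(f"signature {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"signature {name!r} contains duplicate genes")
            if name in self.sets:
                raise ValueError(f"duplicate signature name {name!r}")
            self.sets[name] = genes
        self.lineage: dict[str, str] = dict(lineage or {})
        for name in self.lineage:
            if name not in self.sets:
                raise ValueError(f"lineage tag for unknown signature {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, SignatureSet)
            and self.sets == other.sets
            and self.lineage == other.lineage
        )

    def __repr__(self) -> str:
        return f"SignatureSet({len(self.sets)} sets)"


@dataclass
class EnrichmentMatrix:
    """Signatures x samples matrix of ssGSEA enrichment scores."""

    scores: pd.DataFrame
    alpha: float = 0.25
    normalized: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValueError("enrichment matrix contains non-finite values")

    def row(self, name: str) -> pd.Series:
        if name not in self.scores.index:
            raise KeyError(f"signature row {name!r} not present in enrichment matrix")
        return self.scores.loc[name]


@dataclass
class CompositeScores:
    """Per-sample TAM, T and TME-hot composite scores with provenance."""

    table: pd.DataFrame  # columns: tam_score, t_score, tme_hot
    provenance: dict[str, list[str]] = field(default_factory=dict)

    @property
    def tme_hot(self) -> pd.Series:
        return self.table["tme_hot"]


@dataclass
class SimTruth:
    """Ground truth attached to simulated data."""

    seed: int
    hot_fraction: pd.Series | None = None            # per bulk sample, in [0, 1]
    planted_markers: dict[str, list[str]] | None = None  # cluster -> genes
    planted_tme_gene: tuple[str, float] | None = None    # (gene id, slope vs hot fraction)
    planted_log_hr: float | None = None

    def __post_init__(self) -> None:
        if self.hot_fraction is not None:
            f = np.asarray(self.hot_fraction, dtype=float)
            if ((f < 0) | (f > 1)).any():
                raise ValueError("hot_fraction outside [0, 1]")

    def to_json(self) -> str:
        payload: dict = {"seed": self.seed, "planted_log_hr": self.planted_log_hr}
        if self.hot_fraction is not None:
            payload["hot_fraction"] = {k: float(v) for k, v in self.hot_fraction.items()}
        if self.planted_markers is not None:
            payload["planted_markers"] = self.planted_markers
        if self.planted_tme_gene is not None:
            payload["planted_tme_gene"] = {
                "gene": self.planted_tme_gene[0],
                "slope": self.planted_tme_gene[1],
            }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        payload = json.loads(text)
        hot = payload.get("hot_fraction")
        gene = payload.get("planted_tme_gene")
        return cls(
            seed=payload["seed"],
            hot_fraction=pd.Series(hot) if hot is not None else None,
            planted_markers=payload.get("planted_markers"),
            planted_tme_gene=(gene["gene"], gene["slope"]) if gene else None,
            planted_log_hr=payload.get("planted_log_hr"),
        )


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Check a cell annotation table (index = cell, columns cluster, lineage)."""
    for col in ("cluster", "lineage"):
        if col not in ann.columns:
            raise ValueError(f"annotation missing column {col!r}")
    if ann.index.has_duplicates:
        raise ValueError("annotation has duplicate cell ids")
    if ann[["cluster", "lineage"]].isna().any().any():
        raise ValueError("annotation contains missing labels")
    return ann


def validate_survival(surv: pd.DataFrame) -> pd.DataFrame:
    """Check a survival table (index = sample, columns time, event, ...)."""
    for col in ("time", "event"):
        if col not in surv.columns:
            raise ValueError(f"survival table missing column {col!r}")
    if surv.index.has_duplicates:
        raise ValueError("survival table has duplicate sample ids")
    if (surv["time"] <= 0).any():
        raise ValueError("survival times must be strictly positive")
    if not surv["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0 or 1")
    return surv
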