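"""Readers, writers and pipeline configuration.

Formats: expression matrices as TSV/CSV (genes in rows, header row of sample
ids) or MatrixMarket triplets with ``.rows.txt`` / ``.cols.txt`` sidecar name
files; gene signatures as GMT (name, description, tab-separated genes, one
set per line); clinical/survival tables, marker tables and results as TSV.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .datatypes import ExpressionMatrix, SignatureSet, validate_survival

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "write_table",
    "load_config",
    "validate_config",
    "default_config",
]


def read_expression(
    path: str | Path,
    fmt: str | None = None,
    *,
    lognorm: bool = False,
    orientation: str = "genes_in_rows",
) -> ExpressionMatrix:
    """Read an expression matrix from TSV, CSV or MatrixMarket triplet.

    The MTX path expects ``<path>.rows.txt`` and ``<path>.cols.txt`` name
    files next to the matrix. ``orientation="units_in_rows"`` transposes on
    read.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(path.suffix)
        if fmt is None:
            raise ValueError(f"cannot infer format from suffix {path.suffix!r}")
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0, header=0)
        except (pd.errors.ParserError, ValueError) as exc:
            raise ValueError(f"failed to parse {path}: {exc}") from exc
        non_numeric = df.columns[
            [not np.issubdtype(dt, np.number) for dt in df.dtypes]
        ].tolist()
        if non_numeric:
            raise ValueError(f"non-numeric columns in {path}: {non_numeric}")
    elif fmt == "mtx":
        rows_file = path.with_suffix(path.suffix + ".rows.txt")
        cols_file = path.with_suffix(path.suffix + ".cols.txt")
        for f in (rows_file, cols_file):
            if not f.exists():
                raise FileNotFoundError(f"missing MTX name sidecar file {f}")
        mat = spio.mmread(path)
        rows = rows_file.read_text().splitlines()
        cols = cols_file.read_text().splitlines()
        dense = mat.toarray() if sparse.issparse(mat) else np.asarray(mat)
        if dense.shape != (len(rows), len(cols)):
            raise ValueError(
                f"matrix shape {dense.shape} does not match name files "
                f"({len(rows)} rows, {len(cols)} cols)"
            )
        df = pd.DataFrame(dense, index=rows, columns=cols)
    else:
        raise ValueError(f"unknown expression format {fmt!r}")
    if orientation == "units_in_rows":
        df = df.T
    elif orientation != "genes_in_rows":
        raise ValueError("orientation must be 'genes_in_rows' or 'units_in_rows'")
    return ExpressionMatrix(df, lognorm=lognorm)


def write_expression(
    expr: ExpressionMatrix, path: str | Path, fmt: str | None = None
) -> None:
    """Write an expression matrix as TSV/CSV or MTX triplet with name files."""
    path = Path(path)
    if fmt is None:
        fmt = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(path.suffix, "tsv")
    if fmt in ("tsv", "csv"):
        expr.data.to_csv(path, sep="\t" if fmt == "tsv" else ",")
    elif fmt == "mtx":
        spio.mmwrite(path, sparse.coo_matrix(expr.data.to_numpy()))
        path.with_suffix(path.suffix + ".rows.txt").write_text(
            "\n".join(map(str, expr.genes)) + "\n"
        )
        path.with_suffix(path.suffix + ".cols.txt").write_text(
            "\n".join(map(str, expr.units)) + "\n"
        )
    else:
        raise ValueError(f"unknown expression format {fmt!r}")


def read_gmt(path: str | Path) -> SignatureSet:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    lineage: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT line needs name, description and at "
                f"least one gene ({len(fields)} fields found)"
            )
        name, description, *genes = fields
        genes = [g for g in genes if g]
        if not genes:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = genes
        if description:
            lineage[name] = description
    return SignatureSet(sets, lineage)


def write_gmt(sigs: SignatureSet, path: str | Path) -> None:
    """Write gene sets as GMT, storing the lineage tag in the description."""
    lines = []
    for name, genes in sigs.items():
        description = sigs.lineage.get(name, "na")
        lines.append("\t".join([name, description, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a survival table: TSV with columns sample, time, event, ..."""
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns:
        raise ValueError(f"{path}: clinical table must have a 'sample' column")
    df = df.set_index("sample")
    return validate_survival(df)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


# ---------------------------------------------------------------------------
# Configuration

_SCHEMA: dict[str, dict[str, Any]] = {
    "mode": None,  # "synthetic" | "real"
    "seed": None,
    "atlas": {
        "cells_per_cluster": 40,
        "n_genes": 800,
        "markers_per_cluster": 10,
        "marker_fold": 4.0,
    },
    "bulk": {
        "n_samples": 150,
        "noise_sd": 0.1,
        "tme_gene_slope": 2.0,
        "n_decoys": 29,
    },
    "survival": {"log_hr": -0.5, "baseline_rate": 0.03, "censor_rate": 0.1},
    "markers": {"min_frac": 0.1, "min_log2fc": 0.25, "top_n": 15},
    "ssgsea": {"alpha": 0.25, "normalize": True},
    "scoring": {"nk_mode": "celltype", "rescale_tam": True},
    "screen": {"p_cor": 0.05, "p_cox": 0.05},
    "paths": {
        "expression": None,
        "annotation": None,
        "signatures": None,
        "clinical": None,
        "candidates": None,  # optional: text file of candidate gene ids
    },
}


def default_config(seed: int = 42) -> dict:
    """The fully synthetic demo configuration."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in _SCHEMA.items()}
    cfg["mode"] = "synthetic"
    cfg["seed"] = seed
    del cfg["paths"]
    return cfg


def load_config(path: str | Path) -> dict:
    """Load and validate a YAML pipeline configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    """Reject unknown keys, fill defaults, and range-check parameters."""
    unknown = set(cfg) - set(_SCHEMA)
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    merged: dict[str, Any] = {}
    for key, default in _SCHEMA.items():
        if isinstance(default, dict):
            section = dict(default)
            user = cfg.get(key, {})
            if not isinstance(user, dict):
                raise ValueError(f"section {key!r} must be a mapping")
            bad = set(user) - set(default)
            if bad:
                raise ValueError(f"unknown keys in section {key!r}: {sorted(bad)}")
            section.update(user)
            merged[key] = section
        else:
            merged[key] = cfg.get(key, default)

    mode = merged["mode"]
    if mode not in ("synthetic", "real"):
        raise ValueError("mode must be 'synthetic' or 'real'")
    if merged["seed"] is None:
        raise ValueError("config requires a seed")
    merged["seed"] = int(merged["seed"])

    if not 0 < merged["screen"]["p_cor"] < 1 or not 0 < merged["screen"]["p_cox"] < 1:
        raise ValueError("screen p-value thresholds must lie in (0, 1)")
    if merged["ssgsea"]["alpha"] < 0:
        raise ValueError("ssgsea alpha must be non-negative")
    if not 0 <= merged["survival"]["censor_rate"] < 1:
        raise ValueError("censor_rate must lie in [0, 1)")

    if mode == "real":
        required = ("expression", "clinical", "signatures")
        for name in required:
            p = merged["paths"].get(name)
            if p is None:
                raise ValueError(f"real mode requires paths.{name}")
            if not Path(p).exists():
                raise ValueError(f"paths.{name} does not exist: {p}")
    else:
        merged.pop("paths", None)
    return merged


def demo_config_path() -> Path:
    """Path of the bundled demo configuration."""
    return Path(importlib.resources.files("tmehot") / "data" / "demo.yaml")
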