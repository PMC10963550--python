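"""End-to-end pipeline: simulate (optional) -> markers -> signatures ->
ssGSEA -> composite scores -> gene screen -> survival validation.

Every stage writes its table to the output directory and the run finishes
with ``manifest.json`` recording the configuration, stage seeds, package
version and a SHA-256 checksum per output file. Runs are pure functions of
(config, seed): re-running with the same inputs reproduces every file
bit-for-bit. ``verify_run`` re-hashes the outputs against the manifest so a
tampered intermediate is caught before being reused.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import ExpressionMatrix, SignatureSet, SimTruth
from .enrichment import ssgsea_matrix
from .io import read_clinical, read_expression, read_gmt, write_expression, write_gmt, write_table
from .preprocess import find_markers, lognormalize, qc_filter, top_markers
from .scoring import tme_hot_score
from .screen import (
    compare_groups,
    correlate_with_score,
    cox_fit,
    dichotomize,
    km_logrank,
    screen_genes,
)
from .signatures import curate_signatures, general_genes
from .synthetic import (
    DEFAULT_CLUSTER_LINEAGE,
    DEFAULT_HOT_CLUSTERS,
    mean_profiles,
    simulate_bulk_cohort,
    simulate_cell_atlas,
    simulate_survival,
)

__all__ = [
    "run_pipeline",
    "run_synthetic",
    "verify_run",
    "ChecksumError",
    "PipelineError",
]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending inputs."""


class ChecksumError(RuntimeError):
    """An output file does not match the checksum recorded in the manifest."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def verify_run(out_dir: str | Path) -> None:
    """Check every file in an existing run directory against its manifest."""
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {out_dir}")
    manifest = json.loads(manifest_path.read_text())
    for name, digest in manifest["checksums"].items():
        path = out_dir / name
        if not path.exists():
            raise ChecksumError(f"output file {name} is missing")
        actual = _sha256(path)
        if actual != digest:
            raise ChecksumError(
                f"checksum mismatch for {name}: manifest {digest[:12]}…, "
                f"file {actual[:12]}…"
            )


def _stage(name: str):
    def decorate(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return decorate


def run_pipeline(
    config: dict,
    out_dir: str | Path,
    seed: int | None = None,
    *,
    resume: bool = False,
) -> dict:
    """Execute the full workflow and write all intermediates to ``out_dir``.

    ``seed`` overrides ``config["seed"]``. With ``resume=True`` an existing
    output directory is checksum-verified before anything is reused; a
    mismatch aborts the run.

    Returns a summary dict (also written as ``summary.json``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if resume and (out_dir / "manifest.json").exists():
        verify_run(out_dir)

    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in config.items()}
    if seed is not None:
        cfg["seed"] = int(seed)
    base_seed = int(cfg["seed"])
    # Stage seeds are fixed offsets of the run seed (kept below 2**31).
    seeds = {
        "atlas": base_seed % (2**31),
        "bulk": (base_seed + 1) % (2**31),
        "survival": (base_seed + 2) % (2**31),
    }

    written: list[Path] = []

    def emit(obj, name: str, **kwargs) -> None:
        path = out_dir / name
        if isinstance(obj, ExpressionMatrix):
            write_expression(obj, path)
        elif isinstance(obj, SignatureSet):
            write_gmt(obj, path)
        elif isinstance(obj, pd.DataFrame):
            write_table(obj, path, **kwargs)
        elif isinstance(obj, str):
            path.write_text(obj)
        else:
            path.write_text(json.dumps(obj, indent=2, sort_keys=True))
        written.append(path)

    summary: dict = {"mode": cfg["mode"], "seed": base_seed}

    if cfg["mode"] == "synthetic":
        bulk, sigs, truth, markers_meta = _synthetic_front_end(cfg, seeds, emit)
        candidates = [truth.planted_tme_gene[0]] + [
            g for g in bulk.genes if str(g).startswith("DECOY_")
        ]
        clinical = None
        summary.update(markers_meta)
    else:
        bulk = read_expression(cfg["paths"]["expression"], lognorm=True)
        sigs = read_gmt(cfg["paths"]["signatures"])
        clinical = read_clinical(cfg["paths"]["clinical"])
        truth = None
        cand_path = cfg["paths"].get("candidates")
        if cand_path:
            candidates = [
                g for g in Path(cand_path).read_text().split() if g
            ]
        else:
            candidates = list(bulk.genes)

    em = _score_stage(cfg, bulk, sigs, emit)
    scores = _composite_stage(cfg, em, emit)

    if cfg["mode"] == "synthetic":
        survival = _survival_stage_synthetic(cfg, bulk, truth, seeds, emit)
    else:
        survival = clinical

    screen = _screen_stage(cfg, bulk, candidates, scores, survival, emit)
    km_meta = _km_stage(cfg, bulk, screen, scores, survival, emit)

    n_selected = int(screen["selected"].sum())
    selected = screen.loc[screen["selected"], "gene"].tolist()
    summary.update(
        {
            "n_candidates": len(screen),
            "n_tme_associated": int(screen["tme_associated"].sum()),
            "n_survival_associated": int(screen["survival_associated"].sum()),
            "n_selected": n_selected,
            "selected_genes": selected,
            **km_meta,
        }
    )
    if truth is not None:
        planted = truth.planted_tme_gene[0]
        row = screen.set_index("gene").loc[planted]
        summary["planted_gene"] = {
            "gene": planted,
            "pearson_r": float(row["pearson_r"]),
            "p_correlation": float(row["p_correlation"]),
            "hazard_ratio": float(row["hazard_ratio"]),
            "p_cox": float(row["p_cox"]),
            "selected": bool(row["selected"]),
        }
    emit(summary, "summary.json")

    checksums = {p.name: _sha256(p) for p in sorted(written)}
    manifest = {
        "version": __version__,
        "config": cfg,
        "stage_seeds": seeds,
        "checksums": checksums,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return summary


def run_synthetic(config: dict, seed: int | None = None) -> dict:
    """Run the synthetic workflow in memory and return every stage output.

    Same stages as :func:`run_pipeline` in synthetic mode, without writing
    files. Returns a dict with keys ``bulk, signatures, truth, enrichment,
    scores, survival, screen, meta``.
    """
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in config.items()}
    if seed is not None:
        cfg["seed"] = int(seed)
    base_seed = int(cfg["seed"])
    seeds = {
        "atlas": base_seed % (2**31),
        "bulk": (base_seed + 1) % (2**31),
        "survival": (base_seed + 2) % (2**31),
    }
    noop = lambda obj, name, **kwargs: None  # noqa: E731
    bulk, sigs, truth, meta = _synthetic_front_end(cfg, seeds, noop)
    candidates = [truth.planted_tme_gene[0]] + [
        g for g in bulk.genes if str(g).startswith("DECOY_")
    ]
    em = _score_stage(cfg, bulk, sigs, noop)
    scores = _composite_stage(cfg, em, noop)
    survival = _survival_stage_synthetic(cfg, bulk, truth, seeds, noop)
    screen = _screen_stage(cfg, bulk, candidates, scores, survival, noop)
    return {
        "bulk": bulk,
        "signatures": sigs,
        "truth": truth,
        "enrichment": em,
        "scores": scores,
        "survival": survival,
        "screen": screen,
        "meta": meta,
    }


@_stage("simulate+markers+signatures")
def _synthetic_front_end(cfg, seeds, emit):
    a = cfg["atlas"]
    counts, ann, truth_atlas = simulate_cell_atlas(
        DEFAULT_CLUSTER_LINEAGE,
        a["cells_per_cluster"],
        a["n_genes"],
        a["markers_per_cluster"],
        a["marker_fold"],
        seeds["atlas"],
    )
    emit(ann.reset_index(), "annotation.tsv")

    counts = qc_filter(counts, mito_genes=[])
    expr = lognormalize(counts)
    ann = ann.loc[expr.units]

    m = cfg["markers"]
    cluster_mt = find_markers(
        expr, ann, group_col="cluster", min_frac=m["min_frac"], min_log2fc=m["min_log2fc"]
    )
    lineage_mt = find_markers(
        expr, ann, group_col="lineage", min_frac=m["min_frac"], min_log2fc=m["min_log2fc"]
    )
    emit(cluster_mt, "marker_table.tsv")
    emit(lineage_mt, "lineage_marker_table.tsv")

    clusters = sorted(ann["cluster"].unique())
    top15 = {
        c: top_markers(cluster_mt, c, m["top_n"])
        for c in clusters
        if (cluster_mt["cluster"] == c).any()
    }
    lineage_map = ann.drop_duplicates("cluster").set_index("cluster")["lineage"].to_dict()
    gen_t = general_genes(lineage_mt, "T")
    gen_my = general_genes(lineage_mt, "myeloid")
    sigs, report = curate_signatures(
        top15,
        gen_t,
        gen_my,
        lineage_map,
        treg_cluster="CD4_Trg_FOXP3",
        tam_clusters=["TAM_SPP1/TREM2", "TAM_FOLR2", "TAM_CXCL9"],
        cdc_clusters=["cDC1", "cDC2", "cDC3"],
    )
    emit(report, "curation_report.tsv")

    # Cell-type-level signatures (one per lineage) join the cluster sets.
    celltype_sets = {}
    for lineage in sorted(ann["lineage"].unique()):
        if (lineage_mt["cluster"] == lineage).any():
            celltype_sets[lineage] = top_markers(lineage_mt, lineage, m["top_n"])
    combined = dict(sigs.sets)
    tags = dict(sigs.lineage)
    for name, genes in celltype_sets.items():
        if name not in combined:
            combined[name] = genes
            tags[name] = "cell-type"
    sigs = SignatureSet(combined, tags)
    emit(sigs, "signatures.gmt")

    b = cfg["bulk"]
    profiles = mean_profiles(expr, ann)
    bulk, truth = simulate_bulk_cohort(
        profiles,
        DEFAULT_HOT_CLUSTERS,
        b["n_samples"],
        b["noise_sd"],
        b["tme_gene_slope"],
        seeds["bulk"],
        n_decoys=b["n_decoys"],
    )
    truth.planted_markers = truth_atlas.planted_markers
    emit(bulk, "bulk_expression.tsv")
    emit(truth.to_json(), "sim_truth.json")

    meta = {
        "n_cells_post_qc": int(expr.shape[1]),
        "n_marker_rows": int(len(cluster_mt)),
        "n_signatures": len(sigs),
        "n_curation_removals": int(len(report)),
    }
    return bulk, sigs, truth, meta


@_stage("ssgsea")
def _score_stage(cfg, bulk, sigs, emit):
    em = ssgsea_matrix(
        bulk, sigs, alpha=cfg["ssgsea"]["alpha"], normalize=cfg["ssgsea"]["normalize"]
    )
    emit(em.scores.rename_axis("signature").reset_index(), "enrichment.tsv")
    return em


@_stage("composite-scores")
def _composite_stage(cfg, em, emit):
    scores = tme_hot_score(
        em,
        nk_mode=cfg["scoring"]["nk_mode"],
        rescale_tam=cfg["scoring"]["rescale_tam"],
    )
    emit(scores.table.rename_axis("sample").reset_index(), "composite_scores.tsv")
    return scores


@_stage("simulate-survival")
def _survival_stage_synthetic(cfg, bulk, truth, seeds, emit):
    s = cfg["survival"]
    planted = truth.planted_tme_gene[0]
    covariate = bulk.data.loc[planted]
    covariate.name = planted
    survival = simulate_survival(
        covariate, s["log_hr"], s["baseline_rate"], s["censor_rate"], seeds["survival"]
    )
    truth.planted_log_hr = s["log_hr"]
    emit(survival.rename_axis("sample").reset_index(), "survival.tsv")
    return survival


@_stage("screen")
def _screen_stage(cfg, bulk, candidates, scores, survival, emit):
    cand = bulk.subset_genes(candidates)
    cor = correlate_with_score(cand, scores.tme_hot)
    emit(cor, "correlation.tsv")

    base = survival[["time", "event"]]
    rows = []
    for gene in candidates:
        df = base.copy()
        df[gene] = bulk.data.loc[gene, base.index]
        fit = cox_fit(df, gene)
        rows.append(fit.assign(gene=gene))
    cox_table = pd.concat(rows, ignore_index=True)
    emit(cox_table[["gene", "beta", "hazard_ratio", "ci_low", "ci_high", "p_cox"]],
         "cox_univariate.tsv")

    screen = screen_genes(
        cor, cox_table, p_cor=cfg["screen"]["p_cor"], p_cox=cfg["screen"]["p_cox"]
    )
    emit(screen, "screen_result.tsv")
    return screen


@_stage("survival-validation")
def _km_stage(cfg, bulk, screen, scores, survival, emit):
    # KM on the strongest candidate (largest |r| among selected, falling back
    # to all candidates when nothing was selected).
    pool = screen[screen["selected"]] if screen["selected"].any() else screen
    best = pool.reindex(pool["pearson_r"].abs().sort_values(ascending=False).index)
    gene = best["gene"].iloc[0]
    values = bulk.data.loc[gene, survival.index]
    groups = dichotomize(values)
    km = km_logrank(survival, groups)

    curves = []
    for label, table in sorted(km.curves.items()):
        curves.append(table.assign(group=label))
    emit(pd.concat(curves, ignore_index=True), "km_curves.csv")

    # Responder-group analog: candidate expression in immunologically hot vs
    # cold samples (TME-hot score split at the median).
    hot_groups = dichotomize(scores.tme_hot.loc[values.index])
    stat, p = compare_groups(values, hot_groups)
    return {
        "km_gene": str(gene),
        "logrank_chi2": float(km.logrank_chi2),
        "logrank_p": float(km.logrank_p),
        "hot_vs_cold_rank_sum_p": float(p),
    }
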