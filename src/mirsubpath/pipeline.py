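"""End-to-end orchestration: simulate → build-subpathways → screen/rank → evaluate.

Every stage reads and writes files — no in-memory-only state crosses stage
boundaries — so any stage can be re-run or inspected on its own.  A manifest
(file → sha256) is written at the end; re-running with the same config and
seed reproduces it byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from pathlib import Path
from typing import Any

import pandas as pd

from . import risk as risk_mod
from .graphs import (
    InteractionTable,
    read_pathways_json,
    read_subpathways_json,
    write_pathways_json,
    write_subpathways_json,
)
from .io import (
    align_expression,
    read_clinical_tsv,
    read_expression_tsv,
    write_clinical_tsv,
    write_expression_tsv,
)
from .kgml import parse_kgml_dir
from .robustness import count_subpathway_hits, run_resampled_screens, select_robust
from .screening import (
    exclude_short_survivors,
    make_training_subsets,
    median_survival_strata,
    stratified_split,
)
from .simulate import ScenarioConfig, choose_planted, generate_cohort, generate_interactions, generate_pathways
from .subpathways import build_subpathways

logger = logging.getLogger(__name__)

_INPUT_KEYS = {
    "pathways_json", "kgml_dir", "interactions_tsv",
    "mirna_expr_tsv", "gene_expr_tsv", "clinical_tsv",
}
_PARAM_DEFAULTS: dict[str, Any] = {
    "k": 3,
    "min_genes": 3,
    "min_mirnas": 1,
    "evidence": ["low-throughput"],
    "min_months": 1.0,
    "train_frac": 76 / 112,
    "n_subsets": 100,
    "subset_frac": 0.5,
    "alpha_feature": 0.05,
    "alpha_subpathway": 0.05,
    "selection_mode": "top_n",
    "selection_value": 3,
    "seed": 0,
}


def validate_config(cfg: dict) -> dict:
    """Fill parameter defaults; reject unknown keys and missing inputs."""
    known = _INPUT_KEYS | set(_PARAM_DEFAULTS)
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    out = {**_PARAM_DEFAULTS, **cfg}
    if "pathways_json" not in out and "kgml_dir" not in out:
        raise ValueError("config needs 'pathways_json' or 'kgml_dir'")
    for key in ("interactions_tsv", "mirna_expr_tsv", "gene_expr_tsv", "clinical_tsv"):
        if key not in out:
            raise ValueError(f"config missing required input {key!r}")
    for key in _INPUT_KEYS & set(out):
        if not Path(out[key]).exists():
            raise ValueError(f"input {key} does not exist: {out[key]}")
    return out


def simulate_scenario(cfg: ScenarioConfig, outdir: str | Path,
                      k: int = 3, min_genes: int = 3, min_mirnas: int = 1) -> dict:
    """Generate one synthetic scenario and write it in the pipeline's formats.

    Returns a pipeline config dict pointing at the written files; the planted
    subpathway ids land in ``truth.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pathways = generate_pathways(cfg)
    interactions = generate_interactions(pathways, cfg)
    subs = build_subpathways(pathways, interactions, k=k, min_genes=min_genes, min_mirnas=min_mirnas)
    planted = choose_planted(subs, cfg)
    mirna_expr, gene_expr, clin = generate_cohort(subs, planted, cfg)

    write_pathways_json(pathways, outdir / "pathways.json")
    interactions.write_tsv(outdir / "interactions.tsv")
    write_expression_tsv(mirna_expr, outdir / "mirna_expr.tsv")
    write_expression_tsv(gene_expr, outdir / "gene_expr.tsv")
    write_clinical_tsv(clin, outdir / "clinical.tsv")
    (outdir / "truth.json").write_text(
        json.dumps(
            {"planted": sorted(planted), "scenario": dataclasses.asdict(cfg)},
            indent=1, sort_keys=True,
        )
        + "\n"
    )
    return {
        "pathways_json": str(outdir / "pathways.json"),
        "interactions_tsv": str(outdir / "interactions.tsv"),
        "mirna_expr_tsv": str(outdir / "mirna_expr.tsv"),
        "gene_expr_tsv": str(outdir / "gene_expr.tsv"),
        "clinical_tsv": str(outdir / "clinical.tsv"),
        "seed": cfg.seed,
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: dict, outdir: str | Path) -> dict:
    """Run every stage in order; returns the manifest (also written to disk)."""
    cfg = validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_log = outdir / "run_log.jsonl"
    artifacts: list[Path] = []

    def log_stage(stage: str, t0: float, **info: Any) -> None:
        rec = {"stage": stage, "seconds": round(_time.perf_counter() - t0, 3), **info}
        logger.info("stage %s done: %s", stage, info)
        with run_log.open("a") as fh:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")

    # --- subpathway construction -----------------------------------------
    t0 = _time.perf_counter()
    if "pathways_json" in cfg:
        pathways = read_pathways_json(cfg["pathways_json"])
    else:
        pathways = parse_kgml_dir(cfg["kgml_dir"])
    interactions = InteractionTable.read_tsv(cfg["interactions_tsv"])
    subs = build_subpathways(
        pathways, interactions, k=cfg["k"],
        min_genes=cfg["min_genes"], min_mirnas=cfg["min_mirnas"],
        evidence_filter=cfg["evidence"],
    )
    write_subpathways_json(subs, outdir / "subpathways.json")
    artifacts.append(outdir / "subpathways.json")
    log_stage("build_subpathways", t0, n_pathways=len(pathways), n_subpathways=len(subs))

    # --- cohort preparation ----------------------------------------------
    t0 = _time.perf_counter()
    mirna_expr = read_expression_tsv(cfg["mirna_expr_tsv"])
    gene_expr = read_expression_tsv(cfg["gene_expr_tsv"])
    clin = read_clinical_tsv(cfg["clinical_tsv"])
    clin = exclude_short_survivors(clin, min_months=cfg["min_months"])
    mirna_expr = align_expression(mirna_expr, clin)
    gene_expr = align_expression(gene_expr, clin)
    strata = median_survival_strata(clin)
    train_ids, test_ids = stratified_split(
        clin, train_frac=cfg["train_frac"], seed=cfg["seed"], strata=strata
    )
    (outdir / "split.json").write_text(
        json.dumps({"train": train_ids, "test": test_ids}, indent=1) + "\n"
    )
    artifacts.append(outdir / "split.json")
    subsets = make_training_subsets(
        train_ids, strata, n_subsets=cfg["n_subsets"],
        frac=cfg["subset_frac"], seed=cfg["seed"],
    )
    (outdir / "subsets.json").write_text(json.dumps(subsets, indent=1) + "\n")
    artifacts.append(outdir / "subsets.json")
    log_stage("cohort_split", t0, n_train=len(train_ids), n_test=len(test_ids))

    # --- robustness ranking ----------------------------------------------
    t0 = _time.perf_counter()
    clin_idx = clin.set_index(clin["sample_id"].astype(str), drop=False)
    call_lists = run_resampled_screens(
        subsets, mirna_expr, gene_expr, clin, subs,
        alpha_feature=cfg["alpha_feature"],
        alpha_subpathway=cfg["alpha_subpathway"],
        cache_dir=outdir / "subset_cache",
    )
    table = count_subpathway_hits(call_lists)
    table.to_csv(outdir / "robustness.tsv", sep="\t", index=False)
    artifacts.append(outdir / "robustness.tsv")
    selected = select_robust(table, mode=cfg["selection_mode"], value=cfg["selection_value"])
    (outdir / "selected.json").write_text(json.dumps(selected, indent=1) + "\n")
    artifacts.append(outdir / "selected.json")
    log_stage("robustness", t0, n_selected=len(selected))

    # --- risk models + evaluation ----------------------------------------
    t0 = _time.perf_counter()
    clin_train = clin_idx.loc[train_ids].reset_index(drop=True)
    clin_test = clin_idx.loc[test_ids].reset_index(drop=True)
    by_id = {s.subpathway_id: s for s in subs}
    models = [
        risk_mod.fit_risk_model(by_id[sid], mirna_expr, gene_expr, clin_train)
        for sid in selected
    ]
    combined = (
        risk_mod.combined_fit(models, mirna_expr, gene_expr, clin_train)
        if len(models) >= 2 else None
    )
    risk_mod.write_models_json(models, outdir / "models.json", combined=combined)
    artifacts.append(outdir / "models.json")

    rows = []
    score_rows = []
    for cohort, ids, cl in (("train", train_ids, clin_train), ("test", test_ids, clin_test)):
        m_e = mirna_expr.loc[:, ids]
        g_e = gene_expr.loc[:, ids]
        scored: list[tuple[str, dict[str, float], float]] = [
            (m.subpathway_id, risk_mod.score_samples(m, m_e, g_e), m.training_median)
            for m in models
        ]
        if combined is not None:
            scored.append(("combined", risk_mod.score_combined(combined, m_e, g_e),
                           combined.training_median))
        for model_id, scores, cutoff in scored:
            for s, v in scores.items():
                score_rows.append({"model": model_id, "cohort": cohort,
                                   "sample_id": s, "score": v})
            try:
                cmp_ = risk_mod.compare_risk_groups(scores, cutoff, cl)
                rows.append({
                    "model": model_id, "cohort": cohort,
                    "n_high": sum(g == "high" for g in cmp_.groups.values()),
                    "n_low": sum(g == "low" for g in cmp_.groups.values()),
                    "logrank_chi2": cmp_.logrank_chi2, "logrank_p": cmp_.logrank_p,
                })
            except ValueError as exc:  # degenerate single-group split
                rows.append({
                    "model": model_id, "cohort": cohort, "n_high": 0, "n_low": 0,
                    "logrank_chi2": float("nan"), "logrank_p": float("nan"),
                })
                logger.warning("evaluation degenerate for %s/%s: %s", model_id, cohort, exc)
    pd.DataFrame(rows).to_csv(outdir / "evaluation.tsv", sep="\t", index=False)
    pd.DataFrame(score_rows).to_csv(outdir / "scores.tsv", sep="\t", index=False)
    artifacts.extend([outdir / "evaluation.tsv", outdir / "scores.tsv"])
    log_stage("evaluate", t0, n_models=len(models))

    manifest = {
        "config": {k: cfg[k] for k in sorted(cfg)},
        "files": {p.name: _sha256(p) for p in artifacts},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
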