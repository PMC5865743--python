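"""Synthetic-scenario validation experiments.

These functions run the full analysis on generated cohorts where the ground
truth is known by construction, and report recovery/calibration metrics:

* planted-signal recovery — do the planted prognostic subpathways reach the
  top robustness ranks, and do their risk scores separate held-out samples?
* null calibration — with no planted effect, does the univariate Cox screen
  reject at its nominal rate, and are log-rank p-values on random group
  assignments uniform?

They are ordinary library code (deterministic under their seed arguments)
so the same experiment can be run from tests, scripts, or a shell.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import risk as risk_mod
from .coxph import STATUS_OK
from .io import align_expression
from .robustness import count_subpathway_hits, run_resampled_screens
from .screening import (
    exclude_short_survivors,
    make_training_subsets,
    median_survival_strata,
    screen_features,
    stratified_split,
)
from .simulate import (
    ScenarioConfig,
    choose_planted,
    generate_cohort,
    generate_interactions,
    generate_pathways,
    simulate_expression,
    simulate_survival,
)
from .subpathways import build_subpathways


def planted_recovery_replicate(
    seed: int,
    n_subpathways: int = 40,
    n_train: int = 150,
    n_test: int = 60,
    n_subsets: int = 100,
    alpha: float = 0.05,
    scenario: ScenarioConfig | None = None,
) -> dict:
    """One full pipeline run on a planted scenario; ground-truth metrics.

    Builds subpathways from a generated scenario, keeps the first
    ``n_subpathways`` (deterministic order), plants the scenario's prognostic
    modules, then runs exclusion → stratified split (n_train/n_test) →
    ``n_subsets`` half-subset screens → robustness ranking → risk models for
    the planted subpathways evaluated on the held-out test set.

    Returns planted ids with their robustness counts/dense ranks and the
    held-out log-rank p-value of each planted risk model.
    """
    cfg = scenario if scenario is not None else ScenarioConfig(seed=seed)
    pathways = generate_pathways(cfg)
    interactions = generate_interactions(pathways, cfg)
    subs = build_subpathways(pathways, interactions)[:n_subpathways]
    planted = choose_planted(subs, cfg)
    mirna_expr, gene_expr, clin = generate_cohort(subs, planted, cfg)

    clin = exclude_short_survivors(clin)
    n_cohort = n_train + n_test
    if len(clin) < n_cohort:
        raise ValueError(
            f"only {len(clin)} samples survive the short-follow-up exclusion; "
            f"need {n_cohort}"
        )
    clin = clin.iloc[:n_cohort].reset_index(drop=True)
    mirna_expr = align_expression(mirna_expr, clin)
    gene_expr = align_expression(gene_expr, clin)

    strata = median_survival_strata(clin)
    train_ids, test_ids = stratified_split(
        clin, train_frac=n_train / n_cohort, seed=seed, strata=strata
    )
    subsets = make_training_subsets(
        train_ids, strata, n_subsets=n_subsets, frac=0.5, seed=seed
    )
    call_lists = run_resampled_screens(
        subsets, mirna_expr, gene_expr, clin, subs,
        alpha_feature=alpha, alpha_subpathway=alpha,
    )
    table = count_subpathway_hits(call_lists).set_index("subpathway_id")

    clin_idx = clin.set_index(clin["sample_id"].astype(str), drop=False)
    clin_train = clin_idx.loc[train_ids].reset_index(drop=True)
    clin_test = clin_idx.loc[test_ids].reset_index(drop=True)
    by_id = {s.subpathway_id: s for s in subs}
    heldout_p = {}
    for sid in sorted(planted):
        model = risk_mod.fit_risk_model(
            by_id[sid], mirna_expr.loc[:, train_ids], gene_expr.loc[:, train_ids],
            clin_train,
        )
        scores = risk_mod.score_samples(
            model, mirna_expr.loc[:, test_ids], gene_expr.loc[:, test_ids]
        )
        cmp_ = risk_mod.compare_risk_groups(scores, model.training_median, clin_test)
        heldout_p[sid] = cmp_.logrank_p

    return {
        "planted": sorted(planted),
        "counts": {s: int(table.loc[s, "count"]) for s in sorted(planted)},
        "ranks": {s: int(table.loc[s, "rank"]) for s in sorted(planted)},
        "heldout_logrank_p": heldout_p,
        "robustness": table.reset_index(),
    }


def planted_recovery_experiment(
    master_seed: int, n_replicates: int = 5, top_rank: int = 5, **kwargs
) -> dict:
    """Replicate the planted-recovery run; summarize rank and held-out hits."""
    reps = [
        planted_recovery_replicate(master_seed + 100 * (r + 1), **kwargs)
        for r in range(n_replicates)
    ]
    all_top = [all(rank <= top_rank for rank in rep["ranks"].values()) for rep in reps]
    pvals = [p for rep in reps for p in rep["heldout_logrank_p"].values()]
    return {
        "replicates": reps,
        "frac_all_planted_in_top": float(np.mean(all_top)),
        "frac_heldout_significant": float(np.mean([p < 0.05 for p in pvals])),
        "n_replicates": n_replicates,
        "n_heldout_tests": len(pvals),
    }


def null_screen_rejection_rate(
    master_seed: int,
    n_replicates: int = 200,
    n_features: int = 1000,
    n_samples: int = 200,
    alpha: float = 0.05,
) -> tuple[float, int]:
    """Fraction of features the screen rejects on pure-noise cohorts.

    Each replicate draws a fresh null cohort (no feature–survival
    association) and runs the real miRNA+gene screen; the rate is pooled
    over all converged fits.
    """
    cfg = ScenarioConfig(n_samples=n_samples, effect_size_beta=0.0, seed=master_seed)
    n_mir = n_features // 2
    rejected = 0
    tested = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng([master_seed, 71, rep])
        mirna_expr = simulate_expression(
            [f"m{i}" for i in range(n_mir)], n_samples, rng
        )
        gene_expr = simulate_expression(
            [f"g{i}" for i in range(n_features - n_mir)], n_samples, rng
        )
        clin = simulate_survival(
            np.zeros((1, n_samples)), np.zeros(1), cfg, rng,
            sample_names=list(gene_expr.columns),
        )
        res = screen_features(mirna_expr, gene_expr, clin, alpha=alpha)
        ok = res.results["status"] == STATUS_OK
        rejected += len(res.survival_mirnas) + len(res.survival_genes)
        tested += int(ok.sum())
    return rejected / tested, tested


def logrank_null_uniformity(
    master_seed: int, n_replicates: int = 500, n_samples: int = 100
) -> tuple[float, list[float]]:
    """KS p-value for uniformity of log-rank p-values on random groupings."""
    cfg = ScenarioConfig(n_samples=n_samples, effect_size_beta=0.0, seed=master_seed)
    pvals = []
    for rep in range(n_replicates):
        rng = np.random.default_rng([master_seed, 73, rep])
        clin = simulate_survival(np.zeros((1, n_samples)), np.zeros(1), cfg, rng)
        labels = rng.permutation(
            ["high"] * (n_samples // 2) + ["low"] * (n_samples - n_samples // 2)
        )
        groups = dict(zip(clin["sample_id"], labels))
        _, p = risk_mod.logrank_test(groups, clin)
        pvals.append(p)
    ks = stats.kstest(pvals, "uniform")
    return float(ks.pvalue), pvals
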