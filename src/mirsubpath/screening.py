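"""Cohort preparation and univariate Cox screening of miRNAs and genes.

Stages: drop patients with implausibly short follow-up (< 1 month by
default), stratify the cohort into good/poor survival halves at the median
observed time, draw a stratified train/test split and 100 stratified
half-subsets of the training set, and screen every measured feature with a
univariate Cox model at P < 0.05.

Expression enters the Cox fits as z-scored log2(FPKM+1), so coefficients are
log hazard ratios per standard deviation and comparable across features.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

from .coxph import STATUS_OK, CoxResult, cox_univariate_batch

GOOD, POOR = "good", "poor"
DEFAULT_TRAIN_FRAC = 76 / 112  # mirrors a 112-patient cohort split 76/36


def exclude_short_survivors(clin: pd.DataFrame, min_months: float = 1.0) -> pd.DataFrame:
    """Remove samples with survival time strictly below ``min_months``."""
    keep = clin["time_months"] >= min_months
    removed = int((~keep).sum())
    if removed:
        logger.info("excluded %d samples with survival time < %g months", removed, min_months)
    return clin.loc[keep].reset_index(drop=True)


def median_survival_strata(clin: pd.DataFrame) -> dict[str, str]:
    """Classify samples as poor (below the median observed time) or good.

    Censored samples are classified by their observed (censored) time; the
    boundary (time equal to the median) falls in the good stratum.
    """
    if len(clin) < 2:
        raise ValueError("need at least 2 samples to stratify")
    med = float(np.median(clin["time_months"].to_numpy(float)))
    return {
        str(row.sample_id): (POOR if row.time_months < med else GOOD)
        for row in clin.itertuples()
    }


def _largest_remainder(counts: dict[str, int], frac: float, total: int | None = None) -> dict[str, int]:
    """Allocate `total` picks across strata proportionally to frac·count."""
    keys = sorted(counts)
    quotas = {s: counts[s] * frac for s in keys}
    if total is None:
        total = int(round(sum(quotas.values())))
    base = {s: min(int(math.floor(quotas[s])), counts[s]) for s in keys}
    leftover = total - sum(base.values())
    order = sorted(keys, key=lambda s: (-(quotas[s] - math.floor(quotas[s])), s))
    i = 0
    while leftover > 0 and i < 10 * len(keys):
        s = order[i % len(keys)]
        if base[s] < counts[s]:
            base[s] += 1
            leftover -= 1
        i += 1
    return base


def stratified_split(
    clin: pd.DataFrame,
    train_frac: float = DEFAULT_TRAIN_FRAC,
    seed: int = 0,
    strata: dict[str, str] | None = None,
) -> tuple[list[str], list[str]]:
    """Random stratified train/test split; disjoint and exhaustive.

    Within each good/poor stratum, ``train_frac`` of the samples (largest-
    remainder rounding) go to the training set.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    if strata is None:
        strata = median_survival_strata(clin)
    rng = np.random.default_rng([int(seed), 11])
    by_stratum: dict[str, list[str]] = {}
    for sid in clin["sample_id"].astype(str):
        by_stratum.setdefault(strata[sid], []).append(sid)
    n_train = _largest_remainder({s: len(v) for s, v in by_stratum.items()}, train_frac)
    train, test = [], []
    for s in sorted(by_stratum):
        ids = sorted(by_stratum[s])
        perm = rng.permutation(len(ids))
        picked = {ids[i] for i in perm[: n_train[s]]}
        train.extend(i for i in ids if i in picked)
        test.extend(i for i in ids if i not in picked)
    return train, test


def make_training_subsets(
    train_ids: list[str],
    strata: dict[str, str],
    n_subsets: int = 100,
    frac: float = 0.5,
    seed: int = 0,
) -> list[list[str]]:
    """Independent stratified half-subsets of the training set.

    Each subset keeps the training set's good/poor ratio and has
    ceil(frac · n_train) members (largest-remainder per stratum, without
    replacement within a subset).
    """
    by_stratum: dict[str, list[str]] = {}
    for sid in train_ids:
        by_stratum.setdefault(strata[sid], []).append(sid)
    counts = {s: len(v) for s, v in by_stratum.items()}
    total = math.ceil(frac * len(train_ids))
    take = _largest_remainder(counts, frac, total=total)
    subsets = []
    for j in range(n_subsets):
        rng = np.random.default_rng([int(seed), 13, j])
        picked: list[str] = []
        for s in sorted(by_stratum):
            ids = sorted(by_stratum[s])
            perm = rng.permutation(len(ids))
            chosen = {ids[i] for i in perm[: take[s]]}
            picked.extend(i for i in ids if i in chosen)
        subsets.append(picked)
    return subsets


def transform_expression(expr: pd.DataFrame, standardize: bool = True) -> pd.DataFrame:
    """log2(FPKM+1), optionally z-scored per feature (constant rows left at 0)."""
    z = np.log2(expr.to_numpy(dtype=float) + 1.0)
    if standardize:
        mu = z.mean(axis=1, keepdims=True)
        sd = z.std(axis=1, keepdims=True)
        z = np.where(sd > 1e-12, (z - mu) / np.where(sd > 1e-12, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=expr.index, columns=expr.columns)


def cox_univariate(
    x: pd.Series | np.ndarray,
    clin: pd.DataFrame,
    feature_id: str = "x",
    standardize: bool = False,
) -> CoxResult:
    """Univariate Cox fit of one covariate against the clinical outcome.

    The covariate is used as given unless ``standardize`` is set; degenerate
    (zero-variance) covariates are flagged, not fitted.
    """
    x = np.asarray(x, dtype=float)
    if standardize:
        sd = x.std()
        x = (x - x.mean()) / sd if sd > 1e-12 else x * 0.0
    return cox_univariate_batch(
        x[None, :],
        clin["time_months"].to_numpy(float),
        clin["event"].to_numpy(int),
        [feature_id],
    )[0]


@dataclass(frozen=True)
class ScreenResult:
    survival_mirnas: frozenset[str]
    survival_genes: frozenset[str]
    results: pd.DataFrame  # feature_id, kind, coefficient, se, p_value, status
    m_mirnas: int  # measured miRNA universe
    m_genes: int   # measured gene universe


def _screen_matrix(expr: pd.DataFrame, clin: pd.DataFrame, kind: str) -> pd.DataFrame:
    aligned = expr.loc[:, list(clin["sample_id"].astype(str))]
    z = transform_expression(aligned).to_numpy()
    res = cox_univariate_batch(
        z,
        clin["time_months"].to_numpy(float),
        clin["event"].to_numpy(int),
        list(expr.index),
    )
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in res],
            "kind": kind,
            "coefficient": [r.coefficient for r in res],
            "se": [r.se for r in res],
            "p_value": [r.p_value for r in res],
            "status": [r.status for r in res],
        }
    )


def screen_features(
    mirna_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    clin: pd.DataFrame,
    alpha: float = 0.05,
) -> ScreenResult:
    """Univariate Cox screen of every measured miRNA and gene.

    Returns the survival feature sets (converged fits with Wald P < alpha,
    no multiplicity correction — raw per-feature significance) plus the full
    result table and the measured-universe sizes.
    """
    tab = pd.concat(
        [_screen_matrix(mirna_expr, clin, "miRNA"), _screen_matrix(gene_expr, clin, "gene")],
        ignore_index=True,
    )
    ok = tab["status"] == STATUS_OK
    hit = ok & (tab["p_value"] < alpha)
    return ScreenResult(
        survival_mirnas=frozenset(tab.loc[hit & (tab["kind"] == "miRNA"), "feature_id"]),
        survival_genes=frozenset(tab.loc[hit & (tab["kind"] == "gene"), "feature_id"]),
        results=tab,
        m_mirnas=len(mirna_expr.index),
        m_genes=len(gene_expr.index),
    )
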