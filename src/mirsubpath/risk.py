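"""Subpathway risk scores and survival evaluation.

A subpathway's risk score for a sample is a linear combination of all its
measured miRNA and gene components — significant or not — each weighted by
the component's univariate Cox coefficient refit on the full training set:

    score(sample) = Σ_j  β_j · z_j(sample),

with z the training-standardized log2(FPKM+1) expression.  Samples are split
into high/low risk at the training-set median score (ties go to low risk;
the training median is also the cutoff on held-out data, avoiding test-set
leakage).  Groups are compared with Kaplan–Meier curves and the two-group
log-rank test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .coxph import STATUS_OK
from .graphs import SubpathwayGraph
from .screening import cox_univariate

P_FLOOR = 1e-300  # smaller log-rank p-values are reported as underflow


@dataclass(frozen=True)
class RiskComponent:
    feature_id: str
    kind: str          # "gene" | "miRNA"
    weight: float      # training Cox coefficient (0 when degenerate)
    mean: float        # training mean of log2(x+1)
    sd: float          # training sd of log2(x+1)
    status: str


@dataclass(frozen=True)
class RiskScoreModel:
    """Single-subpathway linear risk model with training-set weights."""

    subpathway_id: str
    components: tuple[RiskComponent, ...]
    training_median: float
    transform: str = "log2p_zscore"

    def to_dict(self) -> dict:
        return {
            "subpathway_id": self.subpathway_id,
            "transform": self.transform,
            "training_median": self.training_median,
            "components": [vars(c) for c in self.components],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RiskScoreModel":
        return cls(
            subpathway_id=d["subpathway_id"],
            components=tuple(RiskComponent(**c) for c in d["components"]),
            training_median=float(d["training_median"]),
            transform=d.get("transform", "log2p_zscore"),
        )


@dataclass(frozen=True)
class CombinedRiskModel:
    """Linear combination of subpathway risk scores, Cox-weighted on training."""

    sub_models: tuple[RiskScoreModel, ...]
    sub_weights: tuple[float, ...]
    training_median: float

    def to_dict(self) -> dict:
        return {
            "sub_models": [m.to_dict() for m in self.sub_models],
            "sub_weights": list(self.sub_weights),
            "training_median": self.training_median,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CombinedRiskModel":
        return cls(
            sub_models=tuple(RiskScoreModel.from_dict(m) for m in d["sub_models"]),
            sub_weights=tuple(float(w) for w in d["sub_weights"]),
            training_median=float(d["training_median"]),
        )


def _component_matrix(
    model: RiskScoreModel, mirna_expr: pd.DataFrame, gene_expr: pd.DataFrame
) -> tuple[np.ndarray, list[str]]:
    """Training-standardized covariates for the model's components, any cohort."""
    samples = list(mirna_expr.columns)
    if list(gene_expr.columns) != samples:
        raise ValueError("miRNA and gene matrices have different sample columns")
    rows = []
    for c in model.components:
        expr = gene_expr if c.kind == "gene" else mirna_expr
        if c.feature_id not in expr.index:
            raise KeyError(
                f"component {c.feature_id!r} of {model.subpathway_id} missing from expression matrix"
            )
        v = np.log2(expr.loc[c.feature_id].to_numpy(float) + 1.0)
        z = (v - c.mean) / c.sd if c.sd > 1e-12 else np.zeros_like(v)
        rows.append(z)
    return np.array(rows), samples


def fit_risk_model(
    sub: SubpathwayGraph,
    mirna_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    clin_train: pd.DataFrame,
) -> RiskScoreModel:
    """Weight every measured subpathway member by its training Cox coefficient.

    Degenerate components get weight 0 and are flagged; a subpathway with no
    usable component at all is an error.
    """
    train_ids = list(clin_train["sample_id"].astype(str))
    members = [(g, "gene") for g in sorted(sub.genes) if g in gene_expr.index]
    members += [(m, "miRNA") for m in sorted(sub.mirnas) if m in mirna_expr.index]
    if not members:
        raise ValueError(f"subpathway {sub.subpathway_id} has no measured members")

    comps = []
    for fid, kind in members:
        expr = gene_expr if kind == "gene" else mirna_expr
        v = np.log2(expr.loc[fid, train_ids].to_numpy(float) + 1.0)
        mean, sd = float(v.mean()), float(v.std())
        z = (v - mean) / sd if sd > 1e-12 else np.zeros_like(v)
        res = cox_univariate(z, clin_train, feature_id=fid)
        weight = res.coefficient if res.status == STATUS_OK else 0.0
        comps.append(RiskComponent(fid, kind, float(weight), mean, sd, res.status))
    if all(c.status != STATUS_OK for c in comps):
        raise ValueError(f"no usable components in subpathway {sub.subpathway_id}")

    model = RiskScoreModel(sub.subpathway_id, tuple(comps), training_median=0.0)
    scores = score_samples(model, mirna_expr.loc[:, train_ids], gene_expr.loc[:, train_ids])
    median = float(np.median(list(scores.values())))
    return RiskScoreModel(sub.subpathway_id, tuple(comps), training_median=median)


def score_samples(
    model: RiskScoreModel, mirna_expr: pd.DataFrame, gene_expr: pd.DataFrame
) -> dict[str, float]:
    """Per-sample linear risk score; a missing component feature is an error."""
    Z, samples = _component_matrix(model, mirna_expr, gene_expr)
    w = np.array([c.weight for c in model.components])
    scores = w @ Z
    return {s: float(v) for s, v in zip(samples, scores)}


def dichotomize(scores: Mapping[str, float], cutoff: float) -> dict[str, str]:
    """high if score > cutoff else low (ties at the cutoff go to low risk)."""
    return {s: ("high" if v > cutoff else "low") for s, v in scores.items()}


def combined_fit(
    models: Sequence[RiskScoreModel],
    mirna_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    clin_train: pd.DataFrame,
) -> CombinedRiskModel:
    """Cox-weight each subpathway's training risk score into a combined model."""
    if len(models) < 2:
        raise ValueError("combined model needs >= 2 sub-models; use the single model directly")
    train_ids = list(clin_train["sample_id"].astype(str))
    m_tr = mirna_expr.loc[:, train_ids]
    g_tr = gene_expr.loc[:, train_ids]
    weights = []
    sub_scores = []
    for m in models:
        sc = score_samples(m, m_tr, g_tr)
        x = np.array([sc[s] for s in train_ids])
        res = cox_univariate(x, clin_train, feature_id=m.subpathway_id)
        weights.append(res.coefficient if res.status == STATUS_OK else 0.0)
        sub_scores.append(x)
    combined = np.array(weights) @ np.array(sub_scores)
    return CombinedRiskModel(
        sub_models=tuple(models),
        sub_weights=tuple(float(w) for w in weights),
        training_median=float(np.median(combined)),
    )


def score_combined(
    model: CombinedRiskModel, mirna_expr: pd.DataFrame, gene_expr: pd.DataFrame
) -> dict[str, float]:
    samples = list(mirna_expr.columns)
    total = np.zeros(len(samples))
    for w, m in zip(model.sub_weights, model.sub_models):
        sc = score_samples(m, mirna_expr, gene_expr)
        total += w * np.array([sc[s] for s in samples])
    return {s: float(v) for s, v in zip(samples, total)}


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve as a right-continuous step function."""

    times: np.ndarray   # event times where the curve steps
    survival: np.ndarray

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class SurvivalComparison:
    groups: dict[str, str]             # sample -> {high, low}
    curves: dict[str, KMCurve]
    logrank_chi2: float
    logrank_p: float


def km_curve(sample_ids: Iterable[str], clin: pd.DataFrame) -> KMCurve:
    """Kaplan–Meier estimate for one group of samples."""
    ids = list(sample_ids)
    if not ids:
        raise ValueError("empty group")
    sub = clin.set_index(clin["sample_id"].astype(str)).loc[ids]
    kmf = KaplanMeierFitter()
    kmf.fit(sub["time_months"].to_numpy(float), sub["event"].to_numpy(int))
    sf = kmf.survival_function_
    return KMCurve(
        times=sf.index.to_numpy(float), survival=sf.iloc[:, 0].to_numpy(float)
    )


def logrank_test(
    groups: Mapping[str, str], clin: pd.DataFrame
) -> tuple[float, float]:
    """Standard two-group log-rank test; returns (chi2, two-sided p)."""
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly 2 non-empty groups, got {labels}")
    clin = clin.set_index(clin["sample_id"].astype(str))
    a = [s for s, g in groups.items() if g == labels[0]]
    b = [s for s, g in groups.items() if g == labels[1]]
    res = _ll_logrank(
        clin.loc[a, "time_months"].to_numpy(float),
        clin.loc[b, "time_months"].to_numpy(float),
        event_observed_A=clin.loc[a, "event"].to_numpy(int),
        event_observed_B=clin.loc[b, "event"].to_numpy(int),
    )
    return float(res.test_statistic), float(max(res.p_value, P_FLOOR))


def compare_risk_groups(
    scores: Mapping[str, float], cutoff: float, clin: pd.DataFrame
) -> SurvivalComparison:
    """Dichotomize at the cutoff and compare high vs low with KM + log-rank."""
    groups = dichotomize(scores, cutoff)
    present = set(groups.values())
    if present != {"high", "low"}:
        raise ValueError(f"degenerate grouping: only {sorted(present)} present")
    curves = {
        g: km_curve([s for s, gg in groups.items() if gg == g], clin)
        for g in ("high", "low")
    }
    chi2, p = logrank_test(groups, clin)
    return SurvivalComparison(groups=groups, curves=curves, logrank_chi2=chi2, logrank_p=p)


def write_models_json(
    models: Sequence[RiskScoreModel], path: str | Path,
    combined: CombinedRiskModel | None = None,
) -> None:
    payload = {"models": [m.to_dict() for m in models]}
    if combined is not None:
        payload["combined"] = combined.to_dict()
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_models_json(path: str | Path) -> tuple[list[RiskScoreModel], CombinedRiskModel | None]:
    payload = json.loads(Path(path).read_text())
    models = [RiskScoreModel.from_dict(d) for d in payload["models"]]
    combined = (
        CombinedRiskModel.from_dict(payload["combined"]) if "combined" in payload else None
    )
    return models, combined


def plot_km(comparison: SurvivalComparison, path: str | Path, title: str = "") -> None:
    """Optional KM plot export (SVG/PNG by file extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in sorted(comparison.curves.items()):
        ax.step(curve.times, curve.survival, where="post", label=f"{label} risk")
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    ax.set_title(title or f"log-rank p = {comparison.logrank_p:.3g}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
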