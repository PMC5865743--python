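"""Single-covariate Cox proportional-hazards fitting, vectorized over features.

The screening stage refits one univariate Cox model per measured feature on
every resampled training subset, so the solver is written to fit a whole
feature matrix at once: a 1-D Newton iteration per feature on the Efron
partial likelihood, with all risk-set sums shared across features.  Efron's
tie approximation reduces to the exact partial likelihood when event times
are distinct.

For a feature ``x`` with per-sample values x_i, observed times t_i and event
indicators d_i, the (Efron) log partial likelihood at coefficient β is

    l(β) = Σ_j [ Σ_{i∈D_j} β x_i − Σ_{l=0}^{d_j−1} log( S_j(β) − (l/d_j) S_{D_j}(β) ) ]

over distinct event times j, where S_j sums exp(βx) over the risk set and
S_{D_j} over the tied events.  The Wald p-value uses the observed information
at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

STATUS_OK = "ok"
STATUS_DEGENERATE = "degenerate"
STATUS_NONCONVERGED = "nonconverged"

_MAX_ABS_BETA = 25.0   # hard clamp during iteration
_MONOTONE_BETA = 10.0  # beyond this the MLE is effectively infinite: no finite
                       # log hazard ratio per SD is credible, flag nonconverged
_MAX_ITER = 60
_GTOL = 1e-9


@dataclass(frozen=True)
class CoxResult:
    """Univariate Cox output for one feature."""

    feature_id: str
    coefficient: float
    se: float
    p_value: float
    status: Literal["ok", "degenerate", "nonconverged"]


def _risk_set_layout(time: np.ndarray, event: np.ndarray):
    """Precompute the ordering and event-time grouping shared by all features.

    Returns (order, group_end, d, tie_mask) where `order` sorts samples by
    descending time, `group_end` indexes (into the ordered arrays) the last
    sample with time >= each distinct event time, and `d` counts tied events.
    """
    order = np.argsort(-time, kind="stable")
    t_sorted = time[order]
    e_sorted = event[order].astype(bool)

    event_times = np.unique(time[event.astype(bool)])[::-1]  # descending
    # last index with t_sorted >= u  ==  count of samples with time >= u - 1
    group_end = np.searchsorted(-t_sorted, -event_times, side="right") - 1
    d = np.array([
        int(np.sum(e_sorted & (t_sorted == u))) for u in event_times
    ])
    event_mask_per_group = [
        np.flatnonzero(e_sorted & (t_sorted == u)) for u in event_times
    ]
    return order, group_end, d, event_mask_per_group


def _loglik_grad_info(beta, Xs, group_end, d, event_idx):
    """Log-likelihood, gradient and observed information, per feature.

    beta: (p,), Xs: (p, n) already in descending-time order.
    """
    p, n = Xs.shape
    eta = beta[:, None] * Xs
    w = np.exp(eta)
    wx = w * Xs
    wxx = wx * Xs
    cw = np.cumsum(w, axis=1)
    cwx = np.cumsum(wx, axis=1)
    cwxx = np.cumsum(wxx, axis=1)

    ll = np.zeros(p)
    grad = np.zeros(p)
    info = np.zeros(p)
    for g_end, dj, idx in zip(group_end, d, event_idx):
        Rw, Rwx, Rwxx = cw[:, g_end], cwx[:, g_end], cwxx[:, g_end]
        Dw = w[:, idx].sum(axis=1)
        Dwx = wx[:, idx].sum(axis=1)
        Dwxx = wxx[:, idx].sum(axis=1)
        sx = Xs[:, idx].sum(axis=1)
        ll += beta * sx
        grad += sx
        for l in range(dj):
            f = l / dj
            denom = Rw - f * Dw
            a1 = Rwx - f * Dwx
            a2 = Rwxx - f * Dwxx
            ll -= np.log(denom)
            grad -= a1 / denom
            info += a2 / denom - (a1 / denom) ** 2
    return ll, grad, info


def cox_univariate_batch(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    feature_ids=None,
) -> list[CoxResult]:
    """Fit one univariate Cox model per row of ``X``.

    Parameters
    ----------
    X : (p, n) covariate matrix (already transformed as desired).
    time, event : length-n survival outcome.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    p, n = X.shape
    if time.shape[0] != n or event.shape[0] != n:
        raise ValueError("covariates and survival outcome have mismatched lengths")
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(p)]

    degenerate = X.std(axis=1) < 1e-12
    if not event.astype(bool).any():
        # no events: partial likelihood is flat; nothing estimable
        degenerate = np.ones(p, dtype=bool)

    results: list[CoxResult | None] = [None] * p
    active = np.flatnonzero(~degenerate)
    for i in np.flatnonzero(degenerate):
        results[i] = CoxResult(feature_ids[i], 0.0, np.nan, 1.0, STATUS_DEGENERATE)
    if active.size == 0:
        return results  # type: ignore[return-value]

    order, group_end, d, event_idx = _risk_set_layout(time, event)
    Xs = X[np.ix_(active, order)]

    beta = np.zeros(active.size)
    converged = np.zeros(active.size, dtype=bool)
    ll, grad, info = _loglik_grad_info(beta, Xs, group_end, d, event_idx)
    for _ in range(_MAX_ITER):
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(info > 0, grad / np.maximum(info, 1e-300), 0.0)
        step = np.clip(step, -2.0, 2.0)
        step = np.where(converged, 0.0, step)
        if np.all(np.abs(step) < 1e-12):
            break
        beta = np.clip(beta + step, -_MAX_ABS_BETA, _MAX_ABS_BETA)
        ll, grad, info = _loglik_grad_info(beta, Xs, group_end, d, event_idx)
        converged |= np.abs(grad) < _GTOL * np.maximum(1.0, info)

    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(info > 0, 1.0 / np.sqrt(np.maximum(info, 1e-300)), np.nan)
        chi2 = np.where(info > 0, beta * beta * info, np.nan)
    pvals = stats.chi2.sf(chi2, df=1)

    ok = converged & (np.abs(beta) < _MONOTONE_BETA) & (info > 0)
    for j, i in enumerate(active):
        if ok[j]:
            results[i] = CoxResult(
                feature_ids[i], float(beta[j]), float(se[j]),
                float(min(max(pvals[j], 0.0), 1.0)), STATUS_OK,
            )
        else:
            results[i] = CoxResult(
                feature_ids[i], float(beta[j]), float(se[j]) if info[j] > 0 else np.nan,
                np.nan, STATUS_NONCONVERGED,
            )
    return results  # type: ignore[return-value]


def cox_partial_loglik(beta: float, x: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Efron log partial likelihood of a single covariate at a given β.

    Exposed for diagnostics and for grid-style exploration of the likelihood.
    """
    order, group_end, d, event_idx = _risk_set_layout(
        np.asarray(time, float), np.asarray(event)
    )
    Xs = np.asarray(x, float)[None, order]
    ll, _, _ = _loglik_grad_info(np.array([float(beta)]), Xs, group_end, d, event_idx)
    return float(ll[0])
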