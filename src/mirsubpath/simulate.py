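"""Synthetic cohorts with planted prognostic subpathways.

The generator emulates the statistical structure the pipeline assumes: a set
of connected random pathway graphs, a curated-style miRNA–gene interaction
table, non-negative skewed (log-normal, FPKM-like) expression, and
right-censored survival times from a proportional-hazards model in which the
member features of a designated set of "planted" subpathways carry a nonzero
log-hazard effect.  With ``effect_size_beta = 0`` the scenario is an exact
null: no feature is associated with survival.

Planted subpathways behave like co-regulated prognostic modules: their
member features share a per-sample latent activity a_s (pairwise expression
correlation ``within_subpathway_corr`` = ρ on the log scale), and the hazard
is proportional-hazards in the latent activities,

    hazard_i = baseline_hazard · exp( Σ_s (β/√ρ) · a_si ),

scaled so that each planted member feature's *marginal* log hazard ratio per
SD of standardized log2(x+1) expression equals ``effect_size_beta`` = β.
(A naive independent-feature model with β on every member would compound to
per-cohort hazard ratios of e^±10 for realistically sized subpathways —
nothing a survival cohort ever shows.)  Event times are exponential with the
per-sample rate, and censoring times are ``min_followup`` plus an
independent exponential whose rate is solved numerically so the expected
censored fraction matches ``censor_rate``.

Everything is deterministic under the master seed; each artifact draws from
its own fixed-offset substream so the pathway graphs, the interaction table
and the cohort can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .graphs import InteractionTable, PathwayGraph, SubpathwayGraph

_STREAM_PATHWAYS = 1
_STREAM_INTERACTIONS = 2
_STREAM_EXPRESSION = 3
_STREAM_SURVIVAL = 4


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic scenario.

    Defaults describe a desk-scale cohort: 20 pathways of 12 genes (random
    graphs at edge probability 0.25, bridged to connectivity), 60 miRNAs
    targeting each gene independently with probability 0.02, 220 patients
    with a 12-month median baseline survival (hazard ln2/12 per month) and
    ~35% censoring, and a per-feature planted log hazard ratio of 1 per SD.
    """

    n_pathways: int = 20
    genes_per_pathway: int = 12
    edge_prob: float = 0.25
    n_mirnas: int = 60
    interaction_prob: float = 0.02
    n_samples: int = 320
    planted_subpathway_count: int = 3
    effect_size_beta: float = 1.0
    within_subpathway_corr: float = 0.5  # ρ: co-expression of planted members
    baseline_hazard: float = float(np.log(2) / 12)  # per month
    censor_rate: float = 0.35
    min_followup: float = 1.0  # months; floor on censoring times
    low_throughput_frac: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("edge_prob", "interaction_prob", "censor_rate",
                     "low_throughput_frac", "within_subpathway_corr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_pathways", "n_mirnas", "n_samples", "planted_subpathway_count"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.genes_per_pathway < 3:
            raise ValueError(
                "genes_per_pathway must be >= 3 (smaller pathways can never "
                "pass the subpathway size filter)"
            )
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.within_subpathway_corr <= 0:
            raise ValueError("within_subpathway_corr must be in (0, 1]")
        if self.min_followup < 0:
            raise ValueError("min_followup must be >= 0")


def gene_ids(cfg: ScenarioConfig) -> list[str]:
    n = cfg.n_pathways * cfg.genes_per_pathway
    return [f"g{i:04d}" for i in range(n)]


def mirna_ids(cfg: ScenarioConfig) -> list[str]:
    return [f"miR-{i + 1:03d}" for i in range(cfg.n_mirnas)]


def sample_ids(cfg: ScenarioConfig) -> list[str]:
    return [f"S{i:04d}" for i in range(cfg.n_samples)]


def _rng(cfg: ScenarioConfig, stream: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), stream, *map(int, extra)])


def generate_pathways(cfg: ScenarioConfig) -> list[PathwayGraph]:
    """Connected Erdős–Rényi gene graphs with globally unique gene ids.

    Disconnected draws are repaired by adding minimum bridging edges between
    components (one edge per extra component, endpoints drawn at random), so
    ``edge_prob = 0`` yields a random tree.
    """
    all_genes = gene_ids(cfg)
    pathways = []
    for p in range(cfg.n_pathways):
        rng = _rng(cfg, _STREAM_PATHWAYS, p)
        genes = all_genes[p * cfg.genes_per_pathway:(p + 1) * cfg.genes_per_pathway]
        m = len(genes)
        edges: set[tuple[str, str]] = set()
        draws = rng.random((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                if draws[i, j] < cfg.edge_prob:
                    edges.add((genes[i], genes[j]))
        # connectivity repair: bridge components with minimum extra edges
        g = nx.Graph()
        g.add_nodes_from(genes)
        g.add_edges_from(edges)
        comps = sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])
        for a_comp, b_comp in zip(comps, comps[1:]):
            a = a_comp[rng.integers(len(a_comp))]
            b = b_comp[rng.integers(len(b_comp))]
            edges.add((a, b) if a <= b else (b, a))
        pathways.append(
            PathwayGraph.from_parts(
                f"sp{p + 1:03d}", genes, edges, pathway_name=f"synthetic pathway {p + 1}"
            )
        )
    return pathways


def generate_interactions(
    pathways: Sequence[PathwayGraph], cfg: ScenarioConfig
) -> InteractionTable:
    """Independent Bernoulli miRNA→gene interactions with an evidence-class mix."""
    if not pathways:
        raise ValueError("pathways must be non-empty")
    genes = sorted(set().union(*(p.nodes for p in pathways)))
    mirs = mirna_ids(cfg)
    rng = _rng(cfg, _STREAM_INTERACTIONS)
    hit = rng.random((len(mirs), len(genes))) < cfg.interaction_prob
    lowt = rng.random((len(mirs), len(genes))) < cfg.low_throughput_frac
    rows = []
    for i, m in enumerate(mirs):
        for j in np.flatnonzero(hit[i]):
            rows.append((m, genes[j], "low-throughput" if lowt[i, j] else "high-throughput"))
    return InteractionTable(
        pd.DataFrame(rows, columns=["mirna", "gene", "evidence"])
        if rows
        else pd.DataFrame(columns=["mirna", "gene", "evidence"])
    )


def simulate_expression(
    feature_ids: Sequence[str],
    n_samples: int,
    rng: np.random.Generator,
    latent: np.ndarray | None = None,
    loadings: np.ndarray | None = None,
) -> pd.DataFrame:
    """Log-normal FPKM-like matrix (features × samples), feature-specific scale.

    With ``latent`` (n_factors × n_samples) and ``loadings`` (n_features ×
    n_factors, rows scaled so Σ loadings² ≤ 1), features co-vary through the
    shared factors: the log-scale normal score of feature j is
    Σ_f L_jf · a_f + sqrt(1 − Σ_f L_jf²) · ε_j.
    """
    p = len(feature_ids)
    mu = rng.normal(3.0, 1.0, size=p)
    sigma = rng.uniform(0.6, 1.4, size=p)
    scores = rng.standard_normal((p, n_samples))
    if latent is not None and loadings is not None:
        resid = np.sqrt(np.clip(1.0 - (loadings**2).sum(axis=1), 0.0, 1.0))
        scores = loadings @ latent + resid[:, None] * scores
    x = np.exp(mu[:, None] + sigma[:, None] * scores)
    cols = [f"S{i:04d}" for i in range(n_samples)]
    return pd.DataFrame(x, index=list(feature_ids), columns=cols)


def _standardized_log(expr: pd.DataFrame) -> np.ndarray:
    z = np.log2(expr.to_numpy(float) + 1.0)
    mu = z.mean(axis=1, keepdims=True)
    sd = z.std(axis=1, keepdims=True)
    return np.where(sd > 1e-12, (z - mu) / np.where(sd > 1e-12, sd, 1.0), 0.0)


def solve_censoring_rate(
    hazards: np.ndarray, censor_rate: float, min_followup: float
) -> float:
    """Exponential censoring rate c with E[censored fraction] = censor_rate.

    With T ~ Exp(h) and C = min_followup + Exp(c), the censoring probability
    for one sample is exp(−h·min_followup) · c/(c+h); the mean over samples
    is monotone in c, so the root is bracketed and solved with Brent.
    """
    if censor_rate <= 0:
        return 0.0
    cap = float(np.mean(np.exp(-hazards * min_followup)))
    if censor_rate >= cap:
        raise ValueError(
            f"censor_rate={censor_rate} unreachable: events before min_followup "
            f"bound the censored fraction at {cap:.3f}"
        )

    def mean_censored(c: float) -> float:
        return float(np.mean(np.exp(-hazards * min_followup) * c / (c + hazards)))

    lo, hi = 1e-12, 1e12
    return float(brentq(lambda c: mean_censored(c) - censor_rate, lo, hi, xtol=1e-12))


def simulate_survival(
    z: np.ndarray,
    betas: np.ndarray,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    sample_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Right-censored PH survival given standardized covariates and effects."""
    eta = betas @ z if z.ndim == 2 else betas * z
    hazards = cfg.baseline_hazard * np.exp(eta)
    n = hazards.shape[0]
    T = rng.exponential(1.0 / hazards)
    if cfg.censor_rate > 0:
        c = solve_censoring_rate(hazards, cfg.censor_rate, cfg.min_followup)
        C = cfg.min_followup + rng.exponential(1.0 / c, size=n)
        time = np.minimum(T, C)
        event = (T <= C).astype(int)
    else:
        time, event = T, np.ones(n, dtype=int)
    names = list(sample_names) if sample_names is not None else [f"S{i:04d}" for i in range(n)]
    return pd.DataFrame({"sample_id": names, "time_months": time, "event": event})


def generate_cohort(
    subpathways: Sequence[SubpathwayGraph],
    planted: set[str],
    cfg: ScenarioConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Expression matrices and clinical table with planted prognostic effects.

    The members (genes and miRNAs) of each planted subpathway co-express
    through a per-sample latent activity, and the hazard is log-linear in
    those activities with slope effect_size_beta/√ρ — so each planted
    feature's marginal log hazard ratio per SD of log2(x+1) expression is
    ``effect_size_beta``, and every non-planted feature is null.  Returns
    (miRNA expression, gene expression, clinical table).
    """
    known = {s.subpathway_id for s in subpathways}
    unknown = planted - known
    if unknown:
        raise ValueError(f"planted subpathway ids not found: {sorted(unknown)}")

    genes = gene_ids(cfg)
    mirs = mirna_ids(cfg)
    planted_subs = sorted(
        (s for s in subpathways if s.subpathway_id in planted),
        key=lambda s: s.subpathway_id,
    )
    rng_expr = _rng(cfg, _STREAM_EXPRESSION)
    n_factors = len(planted_subs)
    latent = rng_expr.standard_normal((n_factors, cfg.n_samples)) if n_factors else None

    rho = cfg.within_subpathway_corr
    member_of = [
        (set(s.genes), set(s.mirnas)) for s in planted_subs
    ]

    def loadings_for(ids: Sequence[str], side: int) -> np.ndarray:
        L = np.zeros((len(ids), max(n_factors, 1)))
        for f, members in enumerate(member_of):
            mem = members[side]
            for j, fid in enumerate(ids):
                if fid in mem:
                    L[j, f] = np.sqrt(rho)
        # features shared by several planted modules keep unit variance
        norms = np.sqrt((L**2).sum(axis=1))
        over = norms > 1.0
        if over.any():
            L[over] /= norms[over, None]
        return L

    gene_expr = simulate_expression(
        genes, cfg.n_samples, rng_expr, latent=latent, loadings=loadings_for(genes, 0)
    )
    mirna_expr = simulate_expression(
        mirs, cfg.n_samples, rng_expr, latent=latent, loadings=loadings_for(mirs, 1)
    )

    slope = cfg.effect_size_beta / np.sqrt(rho)
    eta_factors = (
        slope * latent if latent is not None else np.zeros((1, cfg.n_samples))
    )
    clin = simulate_survival(
        eta_factors.sum(axis=0)[None, :], np.array([1.0]), cfg,
        _rng(cfg, _STREAM_SURVIVAL), sample_names=sample_ids(cfg),
    )
    return mirna_expr, gene_expr, clin


def choose_planted(
    subpathways: Sequence[SubpathwayGraph], cfg: ScenarioConfig
) -> set[str]:
    """Deterministic planted set: one subpathway per parent pathway (so the
    planted signals sit in disjoint gene universes), taking the parents whose
    largest region is biggest — planted modules should have the scale of a
    typical curated subpathway, not be the smallest region that squeaked past
    the size filter."""
    best: dict[str, SubpathwayGraph] = {}
    for s in subpathways:
        cur = best.get(s.parent_pathway)
        if cur is None or (s.n_genes + s.n_mirnas, s.subpathway_id) > (cur.n_genes + cur.n_mirnas, cur.subpathway_id):
            best[s.parent_pathway] = s
    parents = sorted(
        best, key=lambda p: (-(best[p].n_genes + best[p].n_mirnas), p)
    )[: cfg.planted_subpathway_count]
    if len(parents) < cfg.planted_subpathway_count:
        raise ValueError(
            f"only {len(parents)} pathways yielded subpathways; cannot plant "
            f"{cfg.planted_subpathway_count}"
        )
    return {best[p].subpathway_id for p in parents}
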