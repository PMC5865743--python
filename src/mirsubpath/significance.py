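"""The integrated hypergeometric statistic for survival-related subpathways.

Genes and miRNAs are pooled into a single urn of all measured features
(N = m_g + m_mir).  A subpathway contributes K = t_g + t_mir member features;
the Cox screen draws n = n_g + n_mir survival features from the urn, of which
r = r_g + r_mir land inside the subpathway.  The reported p-value is the
exact upper tail

    P = P(X >= r),   X ~ Hypergeometric(N, K, n)
      = 1 − Σ_{k=0}^{r−1} C(K, k) C(N−K, n−k) / C(N, n),

i.e. the chance that a random draw of n features overlaps the subpathway at
least as much as observed.  Subpathway member counts are restricted to
measured features so the urn model stays coherent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .graphs import SubpathwayGraph


@dataclass(frozen=True)
class HypergeomInputs:
    """The eight counts of the pooled gene/miRNA urn model."""

    m_g: int    # measured genes
    m_mir: int  # measured miRNAs
    n_g: int    # survival genes
    n_mir: int  # survival miRNAs
    t_g: int    # measured subpathway genes
    t_mir: int  # measured subpathway miRNAs
    r_g: int    # survival genes inside the subpathway
    r_mir: int  # survival miRNAs inside the subpathway

    def validate(self) -> None:
        for name in ("m_g", "m_mir", "n_g", "n_mir", "t_g", "t_mir", "r_g", "r_mir"):
            if getattr(self, name) < 0:
                raise ValueError(f"count {name} is negative: {getattr(self, name)}")
        if self.r_g > min(self.n_g, self.t_g):
            raise ValueError(f"r_g={self.r_g} exceeds min(n_g={self.n_g}, t_g={self.t_g})")
        if self.r_mir > min(self.n_mir, self.t_mir):
            raise ValueError(
                f"r_mir={self.r_mir} exceeds min(n_mir={self.n_mir}, t_mir={self.t_mir})"
            )
        if self.t_g > self.m_g:
            raise ValueError(f"t_g={self.t_g} exceeds universe m_g={self.m_g}")
        if self.t_mir > self.m_mir:
            raise ValueError(f"t_mir={self.t_mir} exceeds universe m_mir={self.m_mir}")
        if self.n_g > self.m_g:
            raise ValueError(f"n_g={self.n_g} exceeds universe m_g={self.m_g}")
        if self.n_mir > self.m_mir:
            raise ValueError(f"n_mir={self.n_mir} exceeds universe m_mir={self.m_mir}")


@dataclass(frozen=True)
class SubpathwayCall:
    subpathway_id: str
    p_value: float
    inputs: HypergeomInputs
    significant: bool


def pooled_upper_tail(N, K, n, r) -> np.ndarray:
    """Vectorized P(X >= r) for X ~ Hypergeometric(N, K, n).

    Degenerate draws (r = 0, empty subpathway or empty survival set) give
    P = 1: no overlap evidence is never significant.
    """
    N, K, n, r = np.broadcast_arrays(
        np.atleast_1d(N), np.atleast_1d(K), np.atleast_1d(n), np.atleast_1d(r)
    )
    p = stats.hypergeom.sf(r - 1, N, K, n)
    p = np.where((r == 0) | (K == 0) | (n == 0), 1.0, p)
    return np.clip(p, 0.0, 1.0)


def hypergeom_pvalue(h: HypergeomInputs) -> float:
    """Exact upper-tail probability of the pooled-urn overlap."""
    h.validate()
    return float(
        pooled_upper_tail(
            h.m_g + h.m_mir, h.t_g + h.t_mir, h.n_g + h.n_mir, h.r_g + h.r_mir
        )[0]
    )


def tally_overlaps(
    sub: SubpathwayGraph,
    survival_genes: Iterable[str],
    survival_mirnas: Iterable[str],
    universe: tuple[int, int],
    measured_genes: Iterable[str],
    measured_mirnas: Iterable[str],
) -> HypergeomInputs:
    """Count the urn-model inputs for one subpathway.

    ``universe`` is (m_g, m_mir), the measured feature counts.  Subpathway
    members absent from the expression matrices are excluded from every
    count, and the survival sets must lie inside the measured universe.
    """
    measured_genes = set(measured_genes)
    measured_mirnas = set(measured_mirnas)
    survival_genes = set(survival_genes)
    survival_mirnas = set(survival_mirnas)
    if not survival_genes <= measured_genes:
        raise ValueError("survival genes not a subset of measured genes")
    if not survival_mirnas <= measured_mirnas:
        raise ValueError("survival miRNAs not a subset of measured miRNAs")
    t_genes = sub.genes & measured_genes
    t_mirs = sub.mirnas & measured_mirnas
    return HypergeomInputs(
        m_g=universe[0],
        m_mir=universe[1],
        n_g=len(survival_genes),
        n_mir=len(survival_mirnas),
        t_g=len(t_genes),
        t_mir=len(t_mirs),
        r_g=len(t_genes & survival_genes),
        r_mir=len(t_mirs & survival_mirnas),
    )


def identify_survival_subpathways(
    subs: Sequence[SubpathwayGraph],
    survival_genes: Iterable[str],
    survival_mirnas: Iterable[str],
    universe: tuple[int, int],
    measured_genes: Iterable[str],
    measured_mirnas: Iterable[str],
    alpha: float = 0.05,
) -> list[SubpathwayCall]:
    """One hypergeometric call per subpathway, ordered by (p-value, id)."""
    survival_genes = set(survival_genes)
    survival_mirnas = set(survival_mirnas)
    measured_genes = set(measured_genes)
    measured_mirnas = set(measured_mirnas)
    calls = []
    for sub in subs:
        h = tally_overlaps(
            sub, survival_genes, survival_mirnas, universe, measured_genes, measured_mirnas
        )
        p = hypergeom_pvalue(h)
        calls.append(SubpathwayCall(sub.subpathway_id, p, h, p < alpha))
    calls.sort(key=lambda c: (c.p_value, c.subpathway_id))
    return calls


def calls_to_frame(calls: Sequence[SubpathwayCall]) -> pd.DataFrame:
    """Tabular view with a Benjamini–Hochberg column (informational only —
    the significance flag uses the raw p-value)."""
    df = pd.DataFrame(
        {
            "subpathway_id": [c.subpathway_id for c in calls],
            "p_value": [c.p_value for c in calls],
            **{
                f: [getattr(c.inputs, f) for c in calls]
                for f in ("r_g", "r_mir", "t_g", "t_mir", "n_g", "n_mir", "m_g", "m_mir")
            },
            "significant": [c.significant for c in calls],
        }
    )
    if len(df):
        df.insert(2, "bh_fdr", stats.false_discovery_control(df["p_value"], method="bh"))
    else:
        df.insert(2, "bh_fdr", pd.Series(dtype=float))
    return df
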