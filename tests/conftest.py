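"""Shared fixtures and independent oracles for the test suite.

Oracles here are deliberately naive — exhaustive enumeration, direct
summation, grid search — and never reuse the implementation paths they
check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mirsubpath.graphs import PathwayGraph


# ---------------------------------------------------------------- oracles


def hypergeom_upper_tail_oracle(N: int, K: int, n: int, r: int) -> Fraction:
    """1 − Σ_{k=0}^{r−1} C(K,k) C(N−K, n−k) / C(N,n), as an exact rational."""
    if r == 0 or K == 0 or n == 0:
        return Fraction(1)
    den = comb(N, n)
    num = sum(comb(K, k) * comb(N - K, n - k) for k in range(r))
    return 1 - Fraction(num, den)


def kclique_subsets_oracle(g: nx.Graph, k: int) -> set[frozenset]:
    """Maximal node sets with pairwise shortest-path distance <= k, by
    exhaustive enumeration of all 2^n − 1 subsets (n <= ~16).

    Bitmask form: with mask[v] = nodes within distance k of v (including v),
    a subset S is valid iff S ⊆ ∩_{v∈S} mask[v], and maximal iff that
    intersection equals S exactly (any extra node could extend S).
    """
    nodes = sorted(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    dist = dict(nx.all_pairs_shortest_path_length(g, cutoff=k))
    mask = [0] * n
    for v, d in dist.items():
        for u in d:
            mask[idx[v]] |= 1 << idx[u]

    out = set()
    for s in range(1, 1 << n):
        common = ~0
        rest = s
        while rest:
            low = rest & -rest
            common &= mask[low.bit_length() - 1]
            rest ^= low
        if (s & common) == s and common == s:
            out.add(frozenset(nodes[i] for i in range(n) if s >> i & 1))
    return out


def cox_grid_oracle(x, time, event, lo=-6.0, hi=6.0, n_grid=200001) -> float:
    """Direct maximization of the (Breslow=Efron when no ties) partial
    likelihood l(β) = Σ_events (x_i β − log Σ_{risk} e^{x_j β}) on a grid."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    betas = np.linspace(lo, hi, n_grid)
    ll = np.zeros_like(betas)
    for i in np.flatnonzero(event):
        risk = time >= time[i]
        ll += x[i] * betas - np.log(
            np.exp(np.outer(betas, x[risk])).sum(axis=1)
        )
    return float(betas[np.argmax(ll)])


def km_oracle(time, event):
    """Hand product-limit estimator: list of (t, S(t)) at event times."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    s = 1.0
    out = []
    for t in sorted(set(time[event == 1])):
        at_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= (at_risk - d) / at_risk
        out.append((t, s))
    return out


# ---------------------------------------------------------------- fixtures


@pytest.fixture()
def path_graph_6() -> PathwayGraph:
    """Path a–b–c–d–e–f."""
    nodes = list("abcdef")
    return PathwayGraph.from_parts("p1", nodes, list(zip(nodes, nodes[1:])))


@pytest.fixture()
def clinical_4() -> pd.DataFrame:
    return pd.DataFrame(
        {"sample_id": ["s1", "s2", "s3", "s4"],
         "time_months": [1.0, 2.0, 3.0, 4.0],
         "event": [1, 1, 1, 1]}
    )


def random_pathway(rng: np.random.Generator, n_nodes: int, p: float, pid="rp") -> PathwayGraph:
    nodes = [f"n{i}" for i in range(n_nodes)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < p
    ]
    return PathwayGraph.from_parts(pid, nodes, edges)
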