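"""Distance-based k-clique subpathway extraction and miRNA embedding.

A subpathway is a maximal set of genes whose pairwise shortest-path distance
in the *parent pathway graph* is at most ``k`` — equivalently a maximal
clique of the k-th power of the pathway graph.  miRNAs are then embedded:
a miRNA joins a subpathway when a curated interaction links it to at least
one member gene, and only edges to member genes are recorded.  Finally,
regions smaller than the configured gene/miRNA thresholds are dropped.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .graphs import InteractionTable, PathwayGraph, SubpathwayGraph, _norm_edge

DEFAULT_K = 3
DEFAULT_MIN_GENES = 3
DEFAULT_MIN_MIRNAS = 1
DEFAULT_EVIDENCE = frozenset({"low-throughput"})


def extract_k_clique_subpathways(g: PathwayGraph, k: int = DEFAULT_K) -> list[SubpathwayGraph]:
    """All maximal gene sets with pairwise distance ≤ k in the pathway graph.

    Distances are measured in the full parent graph, so two genes joined by a
    short path through non-member genes still count as close.  Results are
    ordered by (size descending, lexicographic gene list) and indexed
    ``<pathway_id>_1, _2, ...`` — a deterministic convention, since region
    identity is otherwise unordered.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    G = g.to_networkx()
    if G.number_of_nodes() == 0:
        return []
    P = nx.power(G, k) if k > 1 else G
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(P)]
    cliques.sort(key=lambda c: (-len(c), c))

    out = []
    edge_set = set(g.edges)
    for i, members in enumerate(cliques, start=1):
        mset = frozenset(members)
        induced = frozenset(
            e for e in edge_set if e[0] in mset and e[1] in mset
        )
        out.append(
            SubpathwayGraph(
                subpathway_id=f"{g.pathway_id}_{i}",
                parent_pathway=g.pathway_id,
                genes=mset,
                gene_edges=induced,
            )
        )
    return out


def embed_mirnas(
    sub: SubpathwayGraph,
    tbl: InteractionTable,
    evidence_filter: Iterable[str] = DEFAULT_EVIDENCE,
) -> SubpathwayGraph:
    """Embed every miRNA that regulates at least one member gene.

    Interactions are restricted to the requested evidence classes (by default
    only interactions verified by low-throughput experiments), and recorded
    edges are restricted to member genes.  Idempotent: re-embedding with the
    same table replaces, never accumulates.
    """
    filtered = tbl.filter_evidence(evidence_filter).df
    hits = filtered[filtered["gene"].isin(sub.genes)]
    edges = frozenset(zip(hits["mirna"], hits["gene"]))
    mirnas = frozenset(m for m, _ in edges)
    return sub.with_mirnas(mirnas, edges)


def filter_subpathways(
    subs: Sequence[SubpathwayGraph],
    min_mirnas: int = DEFAULT_MIN_MIRNAS,
    min_genes: int = DEFAULT_MIN_GENES,
) -> list[SubpathwayGraph]:
    """Drop small regions: keep |miRNAs| >= min_mirnas and |genes| >= min_genes."""
    return [s for s in subs if s.n_mirnas >= min_mirnas and s.n_genes >= min_genes]


def build_subpathways(
    pathways: Sequence[PathwayGraph],
    interactions: InteractionTable,
    k: int = DEFAULT_K,
    min_genes: int = DEFAULT_MIN_GENES,
    min_mirnas: int = DEFAULT_MIN_MIRNAS,
    evidence_filter: Iterable[str] = DEFAULT_EVIDENCE,
) -> list[SubpathwayGraph]:
    """Full construction: extract regions, embed miRNAs, apply the size filter."""
    out: list[SubpathwayGraph] = []
    for pw in pathways:
        subs = extract_k_clique_subpathways(pw, k=k)
        subs = [embed_mirnas(s, interactions, evidence_filter) for s in subs]
        out.extend(filter_subpathways(subs, min_mirnas=min_mirnas, min_genes=min_genes))
    return out


def export_graphml(sub: SubpathwayGraph, path: str | Path) -> None:
    """Write one subpathway (genes + embedded miRNAs) as GraphML."""
    nx.write_graphml(sub.to_networkx(), str(path))
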