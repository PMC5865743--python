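"""Core graph containers: pathway graphs, miRNA-embedded subpathway regions,
and curated miRNA-gene interaction tables.

A :class:`PathwayGraph` is an undirected, unlabeled gene graph (nodes are gene
identifiers, edges are pathway relations).  A :class:`SubpathwayGraph` is a
local region of a pathway — a set of member genes together with the miRNAs
embedded via experimentally supported interactions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

EVIDENCE_CLASSES = frozenset({"low-throughput", "high-throughput"})


def _norm_edge(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class PathwayGraph:
    """Gene-level undirected graph of one pathway."""

    pathway_id: str
    pathway_name: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on node {a!r} in pathway {self.pathway_id}")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(
                    f"edge ({a!r}, {b!r}) references a node missing from pathway {self.pathway_id}"
                )
            if (b, a) in self.edges and a != b:
                raise ValueError(f"edge ({a!r}, {b!r}) stored in both orientations")

    @classmethod
    def from_parts(
        cls, pathway_id: str, nodes: Iterable[str], edges: Iterable[tuple[str, str]],
        pathway_name: str = "",
    ) -> "PathwayGraph":
        return cls(
            pathway_id=pathway_id,
            pathway_name=pathway_name,
            nodes=frozenset(nodes),
            edges=frozenset(_norm_edge(a, b) for a, b in edges if a != b),
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        return g

    def to_dict(self) -> dict:
        return {
            "pathway_id": self.pathway_id,
            "pathway_name": self.pathway_name,
            "nodes": sorted(self.nodes),
            "edges": sorted([list(e) for e in self.edges]),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PathwayGraph":
        return cls.from_parts(
            d["pathway_id"], d["nodes"], [tuple(e) for e in d["edges"]],
            pathway_name=d.get("pathway_name", ""),
        )


@dataclass(frozen=True)
class SubpathwayGraph:
    """A pathway region: member genes, inherited gene edges, embedded miRNAs.

    ``subpathway_id`` follows the ``<pathway_id>_<index>`` convention; the
    index is assigned by the deterministic ordering used at extraction time.
    """

    subpathway_id: str
    parent_pathway: str
    genes: frozenset[str]
    gene_edges: frozenset[tuple[str, str]] = field(default_factory=frozenset)
    mirnas: frozenset[str] = field(default_factory=frozenset)
    mirna_gene_edges: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for a, b in self.gene_edges:
            if a not in self.genes or b not in self.genes:
                raise ValueError(
                    f"gene edge ({a!r}, {b!r}) leaves subpathway {self.subpathway_id}"
                )
        targeted = set()
        for m, g in self.mirna_gene_edges:
            if g not in self.genes:
                raise ValueError(
                    f"miRNA edge ({m!r}, {g!r}) targets a non-member gene in {self.subpathway_id}"
                )
            if m not in self.mirnas:
                raise ValueError(f"miRNA edge for {m!r} without membership in {self.subpathway_id}")
            targeted.add(m)
        if targeted != set(self.mirnas):
            orphans = sorted(set(self.mirnas) - targeted)
            raise ValueError(f"miRNAs without edges in {self.subpathway_id}: {orphans}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirnas)

    def with_mirnas(
        self, mirnas: Iterable[str], edges: Iterable[tuple[str, str]]
    ) -> "SubpathwayGraph":
        return replace(self, mirnas=frozenset(mirnas), mirna_gene_edges=frozenset(edges))

    def to_dict(self) -> dict:
        return {
            "subpathway_id": self.subpathway_id,
            "parent_pathway": self.parent_pathway,
            "genes": sorted(self.genes),
            "gene_edges": sorted([list(e) for e in self.gene_edges]),
            "mirnas": sorted(self.mirnas),
            "mirna_gene_edges": sorted([list(e) for e in self.mirna_gene_edges]),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SubpathwayGraph":
        return cls(
            subpathway_id=d["subpathway_id"],
            parent_pathway=d["parent_pathway"],
            genes=frozenset(d["genes"]),
            gene_edges=frozenset(_norm_edge(a, b) for a, b in d["gene_edges"]),
            mirnas=frozenset(d["mirnas"]),
            mirna_gene_edges=frozenset(tuple(e) for e in d["mirna_gene_edges"]),
        )

    def to_networkx(self) -> nx.Graph:
        """Bipartite-flavoured view for export: gene and miRNA nodes tagged by kind."""
        g = nx.Graph()
        for n in sorted(self.genes):
            g.add_node(n, kind="gene")
        for n in sorted(self.mirnas):
            g.add_node(n, kind="miRNA")
        g.add_edges_from(sorted(self.gene_edges), kind="gene-gene")
        g.add_edges_from(sorted(self.mirna_gene_edges), kind="miRNA-gene")
        return g


class InteractionTable:
    """Curated miRNA→gene interactions with an evidence class per row.

    Wraps a DataFrame with columns ``mirna``, ``gene``, ``evidence``;
    duplicate (mirna, gene) pairs are merged on construction, preferring
    low-throughput evidence (direct experimental support wins).
    """

    COLUMNS = ("mirna", "gene", "evidence")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"interaction table missing columns: {missing}")
        df = df.loc[:, list(self.COLUMNS)].astype(str)
        bad = set(df["evidence"]) - set(EVIDENCE_CLASSES)
        if bad:
            raise ValueError(f"unknown evidence classes: {sorted(bad)}")
        # direct experimental (low-throughput) evidence wins on duplicates
        priority = df["evidence"].map({"low-throughput": 0, "high-throughput": 1})
        df = (
            df.assign(_prio=priority)
            .sort_values(["mirna", "gene", "_prio"], kind="stable")
            .drop_duplicates(["mirna", "gene"], keep="first")
            .drop(columns="_prio")
            .reset_index(drop=True)
        )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def filter_evidence(self, classes: Iterable[str]) -> "InteractionTable":
        classes = set(classes)
        return InteractionTable(self.df[self.df["evidence"].isin(classes)])

    def targets_of(self, mirna: str) -> set[str]:
        return set(self.df.loc[self.df["mirna"] == mirna, "gene"])

    @classmethod
    def from_records(cls, rows: Iterable[tuple[str, str, str]]) -> "InteractionTable":
        return cls(pd.DataFrame(list(rows), columns=list(cls.COLUMNS)))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "InteractionTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def write_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def write_pathways_json(pathways: Iterable[PathwayGraph], path: str | Path) -> None:
    payload = [p.to_dict() for p in pathways]
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_pathways_json(path: str | Path) -> list[PathwayGraph]:
    payload = json.loads(Path(path).read_text())
    return [PathwayGraph.from_dict(d) for d in payload]


def write_subpathways_json(subs: Iterable[SubpathwayGraph], path: str | Path) -> None:
    payload = [s.to_dict() for s in subs]
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_subpathways_json(path: str | Path) -> list[SubpathwayGraph]:
    payload = json.loads(Path(path).read_text())
    return [SubpathwayGraph.from_dict(d) for d in payload]
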