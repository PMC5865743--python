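"""KGML (KEGG Markup Language) pathway parser.

Only gene-type entries are retained: ``<entry type="gene">`` elements become
nodes, ``<relation>`` elements between two gene entries become undirected
edges.  Group, compound and map entries are dropped.  An entry whose ``name``
attribute lists several gene identifiers is expanded to all of them, with a
clique among the members (they act as one interchangeable pathway node), and
any relation touching the entry connects to every member.
"""

from __future__ import annotations

from pathlib import Path

from lxml import etree

from .graphs import PathwayGraph


class KGMLParseError(ValueError):
    """Raised for malformed KGML, with file/line context where available."""


def parse_kgml(source: str | Path | bytes) -> PathwayGraph:
    """Parse one KGML document into a gene-level :class:`PathwayGraph`.

    Parameters
    ----------
    source:
        Path to a ``.xml`` file, or raw XML bytes/text.
    """
    try:
        if isinstance(source, bytes):
            root = etree.fromstring(source)
        elif isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
            root = etree.parse(str(source)).getroot()
        else:
            root = etree.fromstring(source.encode())
    except etree.XMLSyntaxError as exc:
        raise KGMLParseError(f"malformed KGML: {exc}") from exc

    if root.tag != "pathway":
        raise KGMLParseError(f"expected <pathway> root, found <{root.tag}>")

    pathway_id = root.get("number") or root.get("name", "")
    pathway_name = root.get("title", "")

    entry_genes: dict[str, list[str]] = {}
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()

    for entry in root.findall("entry"):
        if entry.get("type") != "gene":
            continue
        genes = entry.get("name", "").split()
        if not genes:
            continue
        entry_genes[entry.get("id", "")] = genes
        nodes.update(genes)
        # multi-gene entries form an internal clique
        for i, a in enumerate(genes):
            for b in genes[i + 1:]:
                if a != b:
                    edges.add((a, b) if a <= b else (b, a))

    for rel in root.findall("relation"):
        g1 = entry_genes.get(rel.get("entry1", ""))
        g2 = entry_genes.get(rel.get("entry2", ""))
        if not g1 or not g2:
            continue  # relation touches a dropped (non-gene) entry
        for a in g1:
            for b in g2:
                if a != b:
                    edges.add((a, b) if a <= b else (b, a))

    return PathwayGraph(
        pathway_id=pathway_id,
        pathway_name=pathway_name,
        nodes=frozenset(nodes),
        edges=frozenset(edges),
    )


def parse_kgml_dir(directory: str | Path) -> list[PathwayGraph]:
    """Parse every ``*.xml`` file in a directory, sorted by filename."""
    paths = sorted(Path(directory).glob("*.xml"))
    return [parse_kgml(p) for p in paths]
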