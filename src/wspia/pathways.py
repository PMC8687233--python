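"""Pathway topology I/O: KGML (KEGG XML) and a plain signed edge-list format.

A pathway is a directed, signed gene network.  Each edge carries a sign
``beta`` (+1 activation/expression, -1 inhibition/repression).  The
perturbation engine consumes the signed adjacency ``beta_matrix`` (rows =
targets, columns = sources) and the per-gene downstream count ``nds``
(out-degree), which normalises each gene's outgoing contribution.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
from lxml import etree

logger = logging.getLogger(__name__)

#: KGML relation subtypes kept as signed edges.  Subtype names *containing*
#: one of these substrings map to the given sign; everything else
#: (binding/association, compound, indirect effect, ...) is dropped and
#: counted in the parse report.
_SUBTYPE_SIGNS = (
    ("activation", +1),
    ("expression", +1),
    ("inhibition", -1),
    ("repression", -1),
)


class PathwayFormatError(ValueError):
    """Raised for malformed pathway files (bad XML, bad edge-list line)."""


@dataclass
class ParseReport:
    """Bookkeeping from a single pathway parse."""

    relations_total: int = 0
    relations_kept: int = 0
    relations_dropped: int = 0
    duplicate_edges: int = 0
    self_loops: int = 0
    non_gene_entries: int = 0

    def __str__(self) -> str:  # compact one-liner for run logs
        return (
            f"relations: {self.relations_total} total, {self.relations_kept} kept, "
            f"{self.relations_dropped} dropped; duplicates: {self.duplicate_edges}; "
            f"self-loops: {self.self_loops}; non-gene entries: {self.non_gene_entries}"
        )


@dataclass
class PathwayGraph:
    """Directed signed gene network.

    Parameters
    ----------
    pathway_id, pathway_name : str
        Identifiers carried through to the results table.
    genes : list of str
        Ordered node labels; order fixes matrix row/column indices.
    edges : list of (source, target, beta)
        ``beta`` is +1 or -1.  Duplicate (source, target) pairs are
        resolved last-wins at construction (a warning is logged).
    """

    pathway_id: str
    pathway_name: str
    genes: list[str]
    edges: list[tuple[str, str, int]]
    report: ParseReport = field(default_factory=ParseReport)

    def __post_init__(self) -> None:
        index = {g: i for i, g in enumerate(self.genes)}
        if len(index) != len(self.genes):
            raise PathwayFormatError(f"{self.pathway_id}: duplicate gene labels")
        deduped: dict[tuple[str, str], int] = {}
        for src, tgt, beta in self.edges:
            if src not in index or tgt not in index:
                raise PathwayFormatError(
                    f"{self.pathway_id}: edge endpoint {src!r}->{tgt!r} not in gene list"
                )
            if beta not in (+1, -1):
                raise PathwayFormatError(f"{self.pathway_id}: beta must be +1/-1, got {beta}")
            if (src, tgt) in deduped:
                self.report.duplicate_edges += 1
                logger.warning("%s: duplicate edge %s->%s, last sign wins", self.pathway_id, src, tgt)
            if src == tgt:
                self.report.self_loops += 1
                logger.info("%s: self-loop on %s", self.pathway_id, src)
            deduped[(src, tgt)] = beta
        self.edges = [(s, t, b) for (s, t), b in deduped.items()]
        self._index = index

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_index(self, gene: str) -> int:
        return self._index[gene]

    @property
    def beta_matrix(self) -> np.ndarray:
        """|genes| x |genes| signed adjacency; entry (i, j) is the effect of gene j on gene i."""
        mat = np.zeros((self.n_genes, self.n_genes), dtype=int)
        for src, tgt, beta in self.edges:
            mat[self._index[tgt], self._index[src]] = beta
        return mat

    @property
    def nds(self) -> dict[str, int]:
        """Downstream-target count (out-degree) per gene; 0 for sinks."""
        counts = dict.fromkeys(self.genes, 0)
        for src, _tgt, _beta in self.edges:
            counts[src] += 1
        return counts

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph(pathway_id=self.pathway_id, pathway_name=self.pathway_name)
        g.add_nodes_from(self.genes)
        for src, tgt, beta in self.edges:
            g.add_edge(src, tgt, beta=beta)
        return g


def downstream_counts(graph: PathwayGraph) -> dict[str, int]:
    """Out-degree per gene (the Nds normaliser of the perturbation recursion)."""
    return graph.nds


def parse_kgml(path: str | os.PathLike) -> PathwayGraph:
    """Parse a KGML (KEGG XML) pathway file into a :class:`PathwayGraph`.

    Entries of type ``gene`` become nodes; multi-gene entries (KGML packs
    several gene IDs into one ``name`` attribute) are expanded to every
    member gene, each inheriting the entry's edges.  Relations whose
    subtype names contain "activation"/"expression" map to beta = +1,
    "inhibition"/"repression" to beta = -1; all other relations are
    dropped and counted in ``graph.report``.  Compound nodes and
    compound-mediated relations are dropped (no propagation through
    compounds).
    """
    path = os.fspath(path)
    try:
        tree = etree.parse(path)
    except (etree.XMLSyntaxError, OSError) as exc:
        raise PathwayFormatError(f"cannot parse KGML file {path!r}: {exc}") from exc
    root = tree.getroot()
    pathway_id = root.get("name", os.path.basename(path)) or os.path.basename(path)
    pathway_name = root.get("title", pathway_id) or pathway_id

    report = ParseReport()
    entry_genes: dict[str, list[str]] = {}
    genes: list[str] = []
    seen: set[str] = set()
    for entry in root.iter("entry"):
        if entry.get("type") != "gene":
            report.non_gene_entries += 1
            continue
        members = (entry.get("name") or "").split()
        entry_genes[entry.get("id", "")] = members
        for g in members:
            if g not in seen:
                seen.add(g)
                genes.append(g)
    if not genes:
        raise PathwayFormatError(f"{path!r}: pathway contains no gene entries")

    edges: list[tuple[str, str, int]] = []
    for rel in root.iter("relation"):
        report.relations_total += 1
        sign = None
        for sub in rel.iter("subtype"):
            name = (sub.get("name") or "").lower()
            for key, s in _SUBTYPE_SIGNS:
                if key in name:
                    sign = s
                    break
            if sign is not None:
                break
        src_members = entry_genes.get(rel.get("entry1", ""))
        tgt_members = entry_genes.get(rel.get("entry2", ""))
        if sign is None or not src_members or not tgt_members:
            report.relations_dropped += 1
            continue
        report.relations_kept += 1
        for src in src_members:
            for tgt in tgt_members:
                edges.append((src, tgt, sign))

    return PathwayGraph(pathway_id, pathway_name, genes, edges, report=report)


def parse_edge_list(path: str | os.PathLike) -> PathwayGraph:
    """Parse the plain signed edge-list format.

    One edge per line: ``source<TAB>target<TAB>sign`` with sign in
    {+1, -1, 1}.  Comment lines starting with ``#`` may carry metadata as
    ``# pathway_id: xxx`` / ``# pathway_name: xxx``.
    """
    path = os.fspath(path)
    pathway_id = os.path.splitext(os.path.basename(path))[0]
    pathway_name = pathway_id
    genes: list[str] = []
    seen: set[str] = set()
    edges: list[tuple[str, str, int]] = []

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    key = key.strip().lower()
                    if key == "pathway_id":
                        pathway_id = val.strip()
                    elif key == "pathway_name":
                        pathway_name = val.strip()
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise PathwayFormatError(
                    f"{path!r} line {lineno}: expected source<TAB>target<TAB>sign, got {line!r}"
                )
            src, tgt, sign_str = parts
            if sign_str.strip() in ("1", "+1"):
                beta = +1
            elif sign_str.strip() == "-1":
                beta = -1
            else:
                raise PathwayFormatError(
                    f"{path!r} line {lineno}: sign must be +1 or -1, got {sign_str!r}"
                )
            for g in (src, tgt):
                if g not in seen:
                    seen.add(g)
                    genes.append(g)
            edges.append((src, tgt, beta))

    return PathwayGraph(pathway_id, pathway_name, genes, edges)


def write_edge_list(graph: PathwayGraph, path: str | os.PathLike) -> None:
    """Write a graph in the edge-list format (round-trips with :func:`parse_edge_list`)."""
    with open(os.fspath(path), "w", encoding="utf-8") as fh:
        fh.write(f"# pathway_id: {graph.pathway_id}\n")
        fh.write(f"# pathway_name: {graph.pathway_name}\n")
        for src, tgt, beta in graph.edges:
            fh.write(f"{src}\t{tgt}\t{beta:+d}\n")


def load_pathway_dir(directory: str | os.PathLike) -> list[PathwayGraph]:
    """Load every pathway file in a directory (``.xml``/``.kgml`` -> KGML,
    ``.tsv``/``.txt``/``.edges`` -> edge list), sorted by file name."""
    directory = os.fspath(directory)
    graphs: list[PathwayGraph] = []
    for name in sorted(os.listdir(directory)):
        full = os.path.join(directory, name)
        if not os.path.isfile(full):
            continue
        ext = os.path.splitext(name)[1].lower()
        if ext in (".xml", ".kgml"):
            graphs.append(parse_kgml(full))
        elif ext in (".tsv", ".txt", ".edges"):
            graphs.append(parse_edge_list(full))
    if not graphs:
        raise PathwayFormatError(f"no pathway files found in {directory!r}")
    return graphs
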