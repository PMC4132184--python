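"""Tabular formats and in-memory containers for interactome analysis.

Gene/protein identifiers are plain strings (sequence names such as
``W03H9.4`` or locus names such as ``cacn-1``); comparison is
case-sensitive exact match. Interaction networks are simple undirected
graphs backed by :class:`networkx.Graph`, with an ``evidence`` attribute
(``known`` or ``predicted``) on every edge.

All readers accept UTF-8 TSV files; lines starting with ``#`` are
comments. Self-loops are dropped with a warning, duplicate unordered
pairs are collapsed (``known`` evidence wins over ``predicted``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

EVIDENCE_LEVELS = ("known", "predicted")

PHENOTYPE_CATEGORIES = ("normal", "extra_turn", "wandering", "overshoot", "other")


class ParseError(ValueError):
    """A malformed input file (wrong column count, bad value, bad header)."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a domain invariant."""


def validate_gene_id(value: str) -> str:
    """Check a gene/protein identifier: non-empty, no internal whitespace."""
    if not isinstance(value, str) or not value:
        raise ValidationError(f"gene id must be a non-empty string, got {value!r}")
    if any(ch.isspace() for ch in value):
        raise ValidationError(f"gene id may not contain whitespace: {value!r}")
    return value


@dataclass(frozen=True)
class InteractionEdge:
    """An undirected interaction between two distinct genes.

    The pair ``{a, b}`` is unordered: ``InteractionEdge("x", "y")`` and
    ``InteractionEdge("y", "x")`` compare equal and hash identically.
    """

    a: str
    b: str
    evidence: str = "known"
    source: str = ""

    def __post_init__(self):
        validate_gene_id(self.a)
        validate_gene_id(self.b)
        if self.a == self.b:
            raise ValidationError(f"self-interaction rejected: {self.a!r}")
        if self.evidence not in EVIDENCE_LEVELS:
            raise ValidationError(
                f"evidence must be one of {EVIDENCE_LEVELS}, got {self.evidence!r}"
            )
        # canonical endpoint order so the unordered pair hashes consistently
        if self.a > self.b:
            lo, hi = self.b, self.a
            object.__setattr__(self, "a", lo)
            object.__setattr__(self, "b", hi)

    @property
    def pair(self) -> frozenset:
        return frozenset((self.a, self.b))


class ReferenceNetwork:
    """A simple undirected interactome: gene nodes, evidence-typed edges.

    Wraps a :class:`networkx.Graph` and enforces simplicity (no
    self-loops, no parallel edges). Isolated nodes (degree 0) are
    first-class members, because permutation nulls must be able to
    sample from every protein-coding gene, most of which have no
    curated interactions.
    """

    def __init__(self, edges: Iterable[InteractionEdge] = (), nodes: Iterable[str] = ()):
        self._g = nx.Graph()
        for n in nodes:
            self._g.add_node(validate_gene_id(n))
        for e in edges:
            self.add_edge(e)

    # -- construction -------------------------------------------------
    def add_node(self, node: str) -> None:
        self._g.add_node(validate_gene_id(node))

    def add_edge(self, edge: InteractionEdge) -> None:
        """Insert an edge; on duplicate pairs, ``known`` evidence wins."""
        g = self._g
        if g.has_edge(edge.a, edge.b):
            if g.edges[edge.a, edge.b]["evidence"] == "predicted" and edge.evidence == "known":
                g.edges[edge.a, edge.b]["evidence"] = "known"
                g.edges[edge.a, edge.b]["source"] = edge.source
            return
        g.add_edge(edge.a, edge.b, evidence=edge.evidence, source=edge.source)

    @classmethod
    def from_graph(cls, g: nx.Graph, default_evidence: str = "known") -> "ReferenceNetwork":
        """Adopt an existing networkx graph (self-loops rejected)."""
        net = cls()
        for n in g.nodes:
            net.add_node(str(n))
        for u, v, data in g.edges(data=True):
            net.add_edge(
                InteractionEdge(
                    str(u),
                    str(v),
                    evidence=data.get("evidence", default_evidence),
                    source=data.get("source", ""),
                )
            )
        return net

    # -- inspection ---------------------------------------------------
    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> set:
        return set(self._g.nodes)

    @property
    def edges(self) -> set:
        return {
            InteractionEdge(u, v, evidence=d["evidence"], source=d.get("source", ""))
            for u, v, d in self._g.edges(data=True)
        }

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def degree(self, node: str) -> int:
        if node not in self._g:
            raise KeyError(f"node {node!r} not in reference network")
        return self._g.degree[node]

    def has_edge(self, a: str, b: str) -> bool:
        return self._g.has_edge(a, b)

    def neighbors(self, node: str) -> set:
        return set(self._g.neighbors(node))

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReferenceNetwork):
            return NotImplemented
        return self.nodes == other.nodes and {e.pair for e in self.edges} == {
            e.pair for e in other.edges
        }

    def __repr__(self) -> str:
        return f"ReferenceNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass(frozen=True)
class HitRecord:
    """One protein identification from a single TAP-MS run."""

    protein: str
    unique_peptides: int
    replicate: str
    condition: str  # "bait" or "control"

    def __post_init__(self):
        validate_gene_id(self.protein)
        if not isinstance(self.unique_peptides, int) or self.unique_peptides < 1:
            raise ValidationError(
                f"unique_peptides must be an integer >= 1, got {self.unique_peptides!r}"
            )
        if self.condition not in ("bait", "control"):
            raise ValidationError(f"condition must be 'bait' or 'control', got {self.condition!r}")


@dataclass(frozen=True)
class PhenotypeCounts:
    """Per-treatment tallies over the five gonad-arm outcome categories.

    ``treatment`` is a gene id or the literal ``"control"``. A treatment
    whose animals could not be scored (e.g. larval arrest under RNAi) is
    represented with ``n=None`` and all categories ``None``; such
    unscored records are excluded from statistical testing.
    """

    treatment: str
    normal: int | None
    extra_turn: int | None
    wandering: int | None
    overshoot: int | None
    other: int | None
    n: int | None

    def __post_init__(self):
        if self.treatment != "control":
            validate_gene_id(self.treatment)
        cats = self.categories
        if self.n is None:
            if any(c is not None for c in cats):
                raise ValidationError(
                    f"{self.treatment}: unscored record (n=None) must have all-None categories"
                )
            return
        if not isinstance(self.n, int) or self.n < 1:
            raise ValidationError(f"{self.treatment}: n must be an integer >= 1, got {self.n!r}")
        for name, c in zip(PHENOTYPE_CATEGORIES, cats):
            if not isinstance(c, int) or c < 0:
                raise ValidationError(f"{self.treatment}: {name} must be an integer >= 0, got {c!r}")
        if sum(cats) != self.n:
            raise ValidationError(
                f"{self.treatment}: categories sum to {sum(cats)} but n={self.n}"
            )

    @property
    def categories(self) -> tuple:
        return (self.normal, self.extra_turn, self.wandering, self.overshoot, self.other)

    @property
    def scored(self) -> bool:
        return self.n is not None

    @property
    def defective(self) -> int:
        """Animals in any non-normal category."""
        if not self.scored:
            raise ValidationError(f"{self.treatment}: unscored treatment has no counts")
        return self.n - self.normal


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _data_lines(path):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_node_list(path) -> set:
    """Read a one-column companion file of node ids (isolated nodes allowed)."""
    nodes = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 1:
            raise ParseError(f"{path}:{lineno}: expected 1 column, got {len(fields)}")
        nodes.add(validate_gene_id(fields[0].strip()))
    return nodes


def read_edge_list(path, default_evidence: str = "known", nodes_path=None) -> ReferenceNetwork:
    """Read an undirected edge list (TSV, 2-3 columns) into a network.

    Column 3, if present, is the evidence level (``known``/``predicted``);
    otherwise ``default_evidence`` applies. Self-loop rows are dropped
    with a logged warning; duplicate unordered pairs are collapsed with
    ``known`` taking precedence. ``nodes_path`` optionally names a
    one-column companion file declaring additional (possibly isolated)
    nodes.
    """
    if default_evidence not in EVIDENCE_LEVELS:
        raise ValidationError(f"default_evidence must be one of {EVIDENCE_LEVELS}")
    net = ReferenceNetwork()
    n_rows = 0
    warned_extra = False
    for lineno, line in _data_lines(path):
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) == 4:
            # some exports carry a directionality column; interactions
            # are modelled as undirected, so it is dropped
            if not warned_extra:
                logger.warning("%s: 4th column ignored (edges are undirected)", path)
                warned_extra = True
            fields = fields[:3]
        if len(fields) not in (2, 3):
            raise ParseError(f"{path}:{lineno}: expected 2-4 columns, got {len(fields)}")
        a, b = validate_gene_id(fields[0]), validate_gene_id(fields[1])
        n_rows += 1
        if a == b:
            logger.warning("%s:%d: self-loop %r dropped", path, lineno, a)
            net.add_node(a)
            continue
        evidence = default_evidence
        if len(fields) == 3:
            if fields[2] not in EVIDENCE_LEVELS:
                raise ParseError(
                    f"{path}:{lineno}: evidence must be one of {EVIDENCE_LEVELS}, got {fields[2]!r}"
                )
            evidence = fields[2]
        net.add_edge(InteractionEdge(a, b, evidence=evidence))
    if n_rows == 0:
        raise ParseError(f"{path}: empty edge list")
    if nodes_path is not None:
        for n in read_node_list(nodes_path):
            net.add_node(n)
    return net


def write_edge_list(net: ReferenceNetwork, path, nodes_path=None) -> None:
    """Write a network as a 3-column TSV; round-trips with read_edge_list.

    Isolated nodes are written to ``nodes_path`` if given (they cannot
    be represented in the edge list itself).
    """
    edges = sorted(net.edges, key=lambda e: (e.a, e.b))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# a\tb\tevidence\n")
        for e in edges:
            fh.write(f"{e.a}\t{e.b}\t{e.evidence}\n")
    if nodes_path is not None:
        connected = {n for e in edges for n in (e.a, e.b)}
        with open(nodes_path, "w", encoding="utf-8") as fh:
            for n in sorted(net.nodes - connected):
                fh.write(f"{n}\n")


_HIT_HEADER = ["protein", "unique_peptides", "replicate", "condition"]


def read_hit_table(path) -> list:
    """Read a TAP-MS hit table (TSV with header protein/unique_peptides/replicate/condition)."""
    rows = list(_data_lines(path))
    if not rows:
        return []
    lineno, header = rows[0]
    cols = [c.strip() for c in header.split("\t")]
    if cols != _HIT_HEADER:
        raise ParseError(f"{path}:{lineno}: expected header {_HIT_HEADER}, got {cols}")
    records: list[HitRecord] = []
    seen = set()
    for lineno, line in rows[1:]:
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
        protein, peptides, replicate, condition = fields
        try:
            n_pep = int(peptides)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: unique_peptides not an integer: {peptides!r}")
        rec = HitRecord(protein, n_pep, replicate, condition)
        key = (rec.protein, rec.replicate, rec.condition)
        if key in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate (protein,replicate,condition) {key}")
        seen.add(key)
        records.append(rec)
    return records


def write_hit_table(records: Sequence[HitRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_HIT_HEADER) + "\n")
        for r in records:
            fh.write(f"{r.protein}\t{r.unique_peptides}\t{r.replicate}\t{r.condition}\n")


_PHENO_HEADER = ["treatment", *PHENOTYPE_CATEGORIES, "n"]


def read_phenotype_table(path) -> list:
    """Read a phenotype table (counts, or percent cells suffixed with ``%``).

    Percent rows are reconstructed to integer counts with
    :func:`cohesion_screen.rnai.counts_from_percent`. Rows whose ``n``
    cell is empty or ``NA`` are returned as unscored records.
    """
    from .rnai import counts_from_percent  # deferred: rnai imports this module

    rows = list(_data_lines(path))
    if not rows:
        return []
    lineno, header = rows[0]
    cols = [c.strip() for c in header.split("\t")]
    if cols != _PHENO_HEADER:
        raise ParseError(f"{path}:{lineno}: expected header {_PHENO_HEADER}, got {cols}")
    out: list[PhenotypeCounts] = []
    seen = set()
    for lineno, line in rows[1:]:
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) != 7:
            raise ParseError(f"{path}:{lineno}: expected 7 columns, got {len(fields)}")
        treatment = fields[0]
        if treatment in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate treatment {treatment!r}")
        seen.add(treatment)
        if fields[6] in ("", "NA"):
            out.append(PhenotypeCounts(treatment, None, None, None, None, None, None))
            continue
        try:
            n = int(fields[6])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: n not an integer: {fields[6]!r}")
        cells = fields[1:6]
        if any(c.endswith("%") for c in cells):
            if not all(c.endswith("%") for c in cells):
                raise ParseError(f"{path}:{lineno}: mixed percent and count cells")
            percents = [float(c[:-1]) for c in cells]
            out.append(counts_from_percent(percents, n, treatment=treatment))
        else:
            try:
                counts = [int(c) for c in cells]
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer count cell")
            out.append(PhenotypeCounts(treatment, *counts, n))
    return out


def write_phenotype_table(records: Sequence[PhenotypeCounts], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_PHENO_HEADER) + "\n")
        for r in records:
            if r.scored:
                cells = "\t".join(str(c) for c in r.categories)
                fh.write(f"{r.treatment}\t{cells}\t{r.n}\n")
            else:
                fh.write(f"{r.treatment}\t\t\t\t\t\tNA\n")
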