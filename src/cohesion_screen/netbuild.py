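"""Seed-graph construction and parsimony expansion.

Starting from a set of seed proteins (e.g. filtered TAP-MS candidate
interactors), the builder extracts their induced subgraph from a
reference interactome, then optionally expands it to first-order
neighbours under a parsimony rule: a non-seed protein joins the network
only if it interacts with at least ``min_links`` seed members.

Qualification is measured against the original seed set in a single
pass — an added node never helps another candidate qualify — but the
final edge set is the full induced subgraph on seeds plus added nodes,
so added-added edges are included when the reference contains them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .interactome import InteractionEdge, ReferenceNetwork, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ExtendedNetwork:
    """Seed nodes plus parsimony-added neighbours and their induced edges.

    ``provenance`` maps each added node to its number of links to seed
    nodes in the reference. ``dropped_seeds`` records requested seeds
    absent from the reference.
    """

    seed_nodes: set
    added_nodes: set
    edges: set
    provenance: dict = field(default_factory=dict)
    dropped_seeds: set = field(default_factory=set)

    @property
    def nodes(self) -> set:
        return self.seed_nodes | self.added_nodes

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_tally(self) -> dict:
        """Edge counts by endpoint role, for reporting.

        ``seed_seed`` counts edges among seeds, ``added_any`` counts
        edges with at least one added endpoint (the increment the
        expansion contributed under the inclusive reading), and
        ``added_added`` the purely-added subset.
        """
        seed_seed = added_any = added_added = 0
        for e in self.edges:
            in_added = (e.a in self.added_nodes) + (e.b in self.added_nodes)
            if in_added == 0:
                seed_seed += 1
            else:
                added_any += 1
                if in_added == 2:
                    added_added += 1
        return {"seed_seed": seed_seed, "added_any": added_any, "added_added": added_added}


def _induced_edges(reference: ReferenceNetwork, nodes: set) -> set:
    sub = reference.graph.subgraph(nodes)
    return {
        InteractionEdge(u, v, evidence=d["evidence"], source=d.get("source", ""))
        for u, v, d in sub.edges(data=True)
    }


def build_seed_graph(seeds: set, reference: ReferenceNetwork) -> ExtendedNetwork:
    """Induced subgraph of the reference on the seed set.

    Seeds absent from the reference are dropped with a warning and
    recorded in ``dropped_seeds`` (reference snapshots vary); an empty
    seed set, or a seed set entirely absent, is an error.
    """
    if not seeds:
        raise ValidationError("seed set is empty")
    present = {s for s in seeds if s in reference}
    dropped = set(seeds) - present
    if dropped:
        logger.warning("%d seed(s) absent from reference, dropped: %s",
                       len(dropped), ", ".join(sorted(dropped)))
    if not present:
        raise ValidationError("no seed is present in the reference network")
    return ExtendedNetwork(
        seed_nodes=present,
        added_nodes=set(),
        edges=_induced_edges(reference, present),
        provenance={},
        dropped_seeds=dropped,
    )


def expand_parsimony(
    seed_graph: ExtendedNetwork,
    reference: ReferenceNetwork,
    min_links: int = 2,
) -> ExtendedNetwork:
    """Add first-order neighbours linked to >= ``min_links`` seed nodes.

    Single-pass semantics: candidates are judged against the original
    seed set only, so adding one node never qualifies another.
    ``min_links=1`` yields the full first-order neighbourhood.
    """
    if min_links < 1:
        raise ValidationError("min_links must be >= 1")
    seeds = seed_graph.seed_nodes
    counts: dict[str, int] = {}
    for s in seeds:
        for nb in reference.neighbors(s):
            if nb not in seeds:
                counts[nb] = counts.get(nb, 0) + 1
    added = {v for v, c in counts.items() if c >= min_links}
    nodes = seeds | added
    return ExtendedNetwork(
        seed_nodes=set(seeds),
        added_nodes=added,
        edges=_induced_edges(reference, nodes),
        provenance={v: counts[v] for v in added},
        dropped_seeds=set(seed_graph.dropped_seeds),
    )


def write_node_roles(net: ExtendedNetwork, path) -> None:
    """Write a node-role TSV (seed/added plus seed-link count for added nodes)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# node\trole\tseed_links\n")
        for n in sorted(net.seed_nodes):
            fh.write(f"{n}\tseed\t\n")
        for n in sorted(net.added_nodes):
            fh.write(f"{n}\tadded\t{net.provenance[n]}\n")
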