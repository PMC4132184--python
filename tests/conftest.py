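from pathlib import Path

import networkx as nx
import pytest

from cohesion_screen.interactome import (
    InteractionEdge,
    ReferenceNetwork,
    read_edge_list,
)

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def fixture_edge_path() -> Path:
    return DATA / "edges10.tsv"


@pytest.fixture()
def fixture_network(fixture_edge_path) -> ReferenceNetwork:
    """8 nodes, 8 edges; see edges10.tsv for the hand enumeration."""
    return read_edge_list(fixture_edge_path)


@pytest.fixture()
def pentagon_chords() -> ReferenceNetwork:
    """The 5-cycle A-B-C-D-E plus chord B-D, plus isolated path F-G-H."""
    edges = [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("E", "A"),
             ("B", "D"), ("F", "G"), ("G", "H")]
    return ReferenceNetwork(InteractionEdge(a, b) for a, b in edges)


def make_net(edges, nodes=()) -> ReferenceNetwork:
    return ReferenceNetwork(
        (InteractionEdge(a, b) for a, b in edges), nodes=nodes
    )


@pytest.fixture()
def complete_k6() -> ReferenceNetwork:
    g = nx.complete_graph(6)
    return ReferenceNetwork.from_graph(nx.relabel_nodes(g, {i: f"n{i}" for i in g}))
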