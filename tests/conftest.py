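import networkx as nx
import pandas as pd
import pytest

from drugprox.interactome import Interactome
from drugprox.similarity import AssociationNetwork


def make_interactome(edges) -> Interactome:
    g = nx.Graph()
    g.add_edges_from(edges)
    return Interactome(g)


def make_net(edges, stage="similarity") -> AssociationNetwork:
    """Association network from (drug, disease, weight) triples."""
    df = pd.DataFrame(edges, columns=["drug", "disease", "weight"])
    df["similarity"] = df["weight"]
    return AssociationNetwork(df, stage)


@pytest.fixture
def path_graph():
    """A-B-C-D-E path."""
    return make_interactome([("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")])


@pytest.fixture
def k10():
    """Complete graph on n0..n9."""
    g = nx.relabel_nodes(nx.complete_graph(10), {i: f"n{i}" for i in range(10)})
    return Interactome(g)
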