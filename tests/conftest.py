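"""Shared fixtures: tiny networks, ontologies and scenarios built in memory."""

from __future__ import annotations

import networkx as nx
import pytest

from modcons.clustering import ModulePartition
from modcons.edge_scoring import ScoredNetwork
from modcons.go_semantics import AnnotationSet, OntologyDAG
from modcons.integration import IntegratedNetwork
from modcons.orthology import OrthologyMap
from modcons.synthetic_data import ScenarioConfig, generate_scenario


def make_scored(species: str, data_type: str, edges) -> ScoredNetwork:
    net = ScoredNetwork(species=species, data_type=data_type)
    for a, b, w in edges:
        net.add_edge(a, b, w)
    return net


def make_integrated(species: str, edges) -> IntegratedNetwork:
    """edges: iterable of (a, b, weight) or (a, b, weight, provenance)."""
    net = IntegratedNetwork(species=species)
    for row in edges:
        if len(row) == 3:
            a, b, w = row
            prov = frozenset({"ppi"})
        else:
            a, b, w, prov = row
        net.add_edge(a, b, w, prov)
    return net


@pytest.fixture
def chain_dag() -> OntologyDAG:
    """c --is_a--> p: the minimal two-term ontology."""
    g = nx.DiGraph()
    g.add_edge("c", "p", relation="is_a")
    return OntologyDAG(graph=g, namespace="biological_process")


@pytest.fixture
def diamond_dag() -> OntologyDAG:
    """c -> p1 -> r and c -> p2 -> r, all is_a."""
    g = nx.DiGraph()
    for child, parent in [("c", "p1"), ("c", "p2"), ("p1", "r"), ("p2", "r")]:
        g.add_edge(child, parent, relation="is_a")
    return OntologyDAG(graph=g, namespace="biological_process")


@pytest.fixture
def toy_annotations() -> AnnotationSet:
    return AnnotationSet(
        species="A",
        annotations={
            "g1": {"c"},
            "g2": {"p"},
            "g3": {"c", "p"},
        },
    )


@pytest.fixture
def identity_partition() -> ModulePartition:
    return ModulePartition(
        species="A",
        modules={0: frozenset({"a", "b", "c"}), 1: frozenset({"d", "e", "f"})},
        unassigned={"z"},
    )


@pytest.fixture(scope="session")
def small_scenario():
    """A compact two-species scenario used across module tests."""
    cfg = ScenarioConfig(
        seed=11,
        n_genes=400,
        n_modules=25,
        module_size_min=12,
        module_size_max=20,
        between_density=0.004,
        n_experiments=2,
    )
    return generate_scenario(cfg)


def identity_orthology(genes) -> OrthologyMap:
    pairs = {(g, g) for g in genes}
    return OrthologyMap(
        species_a="A",
        species_b="B",
        pairs=pairs,
        provenance={p: "identity" for p in pairs},
    )
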