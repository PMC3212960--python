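"""Combine evidence networks into one weighted network per species.

Evidence types are treated as independent, so the integrated weight of an
edge is the plain sum of its log-likelihood scores across the contributing
networks.  By default co-expression, PPI, positive genetic interaction and
sequence evidence are integrated; negative genetic interactions (which tend
to connect parallel pathways rather than co-members of a process) and the
GO network (used for comparison only) are never integrated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .edge_scoring import ScoredNetwork
from .io_formats import RawEdgeList

logger = logging.getLogger(__name__)

#: evidence tags folded into the default integrated network
DEFAULT_INTEGRATED_TAGS = frozenset({"coexpression", "ppi", "gi_positive", "sequence"})
#: the "no-seqs" robustness variant
NO_SEQUENCE_TAGS = frozenset({"coexpression", "ppi", "gi_positive"})


@dataclass
class IntegratedNetwork:
    """Per-species union of evidence networks with summed LLS weights."""

    species: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    def add_edge(self, a: str, b: str, weight: float, provenance: frozenset[str]) -> None:
        if a == b:
            raise ValueError(f"self-edge not allowed: {a!r}")
        if not provenance:
            raise ValueError("edge provenance must be non-empty")
        self.graph.add_edge(a, b, weight=float(weight), provenance=frozenset(provenance))

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def weight(self, a: str, b: str) -> float:
        return self.graph.edges[a, b]["weight"]

    def provenance(self, a: str, b: str) -> frozenset[str]:
        return self.graph.edges[a, b]["provenance"]

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self):
        """Iterate over (gene_a, gene_b, weight, provenance) with a < b."""
        for a, b, d in self.graph.edges(data=True):
            x, y = sorted((a, b))
            yield x, y, d["weight"], d["provenance"]

    def edge_set(self) -> set[tuple[str, str]]:
        return {(min(a, b), max(a, b)) for a, b in self.graph.edges()}

    def degree(self, gene: str) -> int:
        return self.graph.degree(gene) if gene in self.graph else 0


def integrate(
    networks: list[ScoredNetwork],
    include: frozenset[str] | set[str] = DEFAULT_INTEGRATED_TAGS,
) -> IntegratedNetwork:
    """Sum log-likelihood scores of every edge over the included networks."""
    if not networks:
        raise ValueError("at least one network required")
    species = networks[0].species
    if any(n.species != species for n in networks):
        raise ValueError("cannot integrate networks from different species")
    out = IntegratedNetwork(species=species)
    acc: dict[tuple[str, str], tuple[float, set[str]]] = {}
    for net in networks:
        if net.data_type not in include:
            logger.info("skipping %s network (not in include set)", net.data_type)
            continue
        for a, b, w in net.edges():
            weight, prov = acc.get((a, b), (0.0, set()))
            prov = set(prov)
            prov.add(net.data_type)
            acc[(a, b)] = (weight + w, prov)
    for (a, b), (w, prov) in acc.items():
        out.add_edge(a, b, w, frozenset(prov))
    return out


def exclude_paralog_edges(
    net: IntegratedNetwork, self_hits: RawEdgeList, evalue_cutoff: float = 1e-25
) -> IntegratedNetwork:
    """Remove every edge whose endpoints hit each other at E <= cutoff.

    Robustness variant ("exclude-para"): strips interactions that could be
    explained by sequence similarity alone, regardless of evidence type.
    """
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be positive")
    if self_hits.data_type != "blast_hit":
        raise ValueError("self_hits must be a blast_hit edge list")
    similar: set[tuple[str, str]] = set()
    for a, b, evalue in self_hits.records:
        if a != b and evalue is not None and evalue <= evalue_cutoff:
            similar.add((min(a, b), max(a, b)))
    out = IntegratedNetwork(species=net.species)
    n_removed = 0
    for a, b, w, prov in net.edges():
        if (a, b) in similar:
            n_removed += 1
            continue
        out.add_edge(a, b, w, prov)
    if n_removed:
        logger.info("excluded %d paralog-linked edges", n_removed)
    return out


def subsample_edges(
    net: IntegratedNetwork, keep_fraction: float, seed: int
) -> IntegratedNetwork:
    """Keep an exact-count uniform random subset of edges (coverage trimming)."""
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    edges = sorted(net.edges())
    n_keep = round(keep_fraction * len(edges))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(edges), size=n_keep, replace=False)
    out = IntegratedNetwork(species=net.species)
    for i in sorted(idx):
        a, b, w, prov = edges[i]
        out.add_edge(a, b, w, prov)
    return out
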