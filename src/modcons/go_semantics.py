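"""Wang-style semantic similarity over the Gene Ontology and the GO network.

The GO evidence network connects two genes when their annotation profiles are
semantically close.  Similarity between two terms follows the graph-based
measure of Wang et al.: each term defines a "semantic value" over its ancestral
closure, obtained by propagating a contribution of 1 at the term itself upward
through ``is_a`` / ``part_of`` links, multiplying by a per-relation decay
factor and taking the maximum over paths.  Gene-level similarity is the
best-match average of the term-level similarities of the two annotation sets.

Terms annotating a large fraction of the genome (the root and its immediate
neighbourhood) carry almost no information, so they are removed before any
gene-level computation; genes left without annotations are excluded rather
than scored zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

logger = logging.getLogger(__name__)

#: Canonical decay factors of the Wang measure per relation type.
DEFAULT_WEIGHTS: dict[str, float] = {"is_a": 0.8, "part_of": 0.6}

#: Fraction of a species' genes above which a term is considered uninformative.
DEFAULT_LARGE_TERM_FRACTION = 0.05


@dataclass
class OntologyDAG:
    """Directed acyclic graph of ontology terms.

    ``graph`` holds one directed edge per child -> parent link with a
    ``relation`` attribute (``is_a`` or ``part_of``).  Only a single namespace
    (branch) is kept per instance.
    """

    graph: nx.DiGraph
    namespace: str = "biological_process"

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("ontology graph contains a cycle")

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable from ``term`` by child->parent edges."""
        return nx.descendants(self.graph, term)

    def roots(self) -> set[str]:
        return {t for t in self.graph.nodes if self.graph.out_degree(t) == 0}


@dataclass
class AnnotationSet:
    """Per-gene ontology annotations for one species (unpropagated)."""

    species: str
    annotations: dict[str, set[str]] = field(default_factory=dict)
    #: evidence codes per (gene, term) association
    evidence: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    @property
    def genes(self) -> set[str]:
        return set(self.annotations)

    def terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.annotations.values():
            out |= ts
        return out

    def validate_against(self, dag: OntologyDAG) -> None:
        unknown = self.terms() - dag.terms
        if unknown:
            raise ValueError(f"annotations reference unknown terms: {sorted(unknown)[:5]}")


def s_values(
    term: str, dag: OntologyDAG, weights: dict[str, float] | None = None
) -> dict[str, float]:
    """Semantic contributions of ``term`` to every term in its ancestral closure.

    S(term) = 1 at the term itself; for an ancestor t the contribution is the
    maximum over child edges on paths toward ``term`` of w(relation) * S(child).
    """
    if term not in dag:
        raise KeyError(f"term {term!r} not in ontology")
    weights = DEFAULT_WEIGHTS if weights is None else weights
    for rel, w in weights.items():
        if not 0.0 < w < 1.0:
            raise ValueError(f"weight for {rel!r} must be in (0,1), got {w}")

    closure = dag.ancestors(term) | {term}
    sub = dag.graph.subgraph(closure)
    s: dict[str, float] = {term: 1.0}
    # children precede parents in a topological order of child->parent edges
    for node in nx.topological_sort(sub):
        if node == term:
            continue
        best = 0.0
        for child, _, data in sub.in_edges(node, data=True):
            w = weights.get(data.get("relation", "is_a"))
            if w is None:
                # unknown relation types do not propagate contribution
                continue
            if child in s:
                best = max(best, w * s[child])
        s[node] = best
    return s


def _semantic_value(s: dict[str, float]) -> float:
    return sum(s.values())


def term_similarity(
    t1: str,
    t2: str,
    dag: OntologyDAG,
    weights: dict[str, float] | None = None,
) -> float:
    """Wang similarity of two terms, in [0, 1] and symmetric."""
    s1 = s_values(t1, dag, weights)
    s2 = s_values(t2, dag, weights)
    return _term_similarity_from_svalues(s1, s2)


def _term_similarity_from_svalues(s1: dict[str, float], s2: dict[str, float]) -> float:
    shared = s1.keys() & s2.keys()
    if not shared:
        return 0.0
    num = sum(s1[t] + s2[t] for t in shared)
    return num / (_semantic_value(s1) + _semantic_value(s2))


def gene_similarity(
    g1: str,
    g2: str,
    ann: AnnotationSet,
    dag: OntologyDAG,
    weights: dict[str, float] | None = None,
) -> float:
    """Best-match-average similarity between the annotation sets of two genes."""
    t1 = ann.annotations.get(g1, set())
    t2 = ann.annotations.get(g2, set())
    if not t1 or not t2:
        raise ValueError(f"gene without annotations: {g1 if not t1 else g2!r}")
    sv = {t: s_values(t, dag, weights) for t in t1 | t2}
    return _gene_similarity_from_svalues(t1, t2, sv)


def _gene_similarity_from_svalues(
    t1: set[str], t2: set[str], sv: dict[str, dict[str, float]]
) -> float:
    sim: dict[tuple[str, str], float] = {}
    for a in t1:
        for b in t2:
            sim[(a, b)] = (
                1.0 if a == b else _term_similarity_from_svalues(sv[a], sv[b])
            )
    fwd = sum(max(sim[(a, b)] for b in t2) for a in t1)
    bwd = sum(max(sim[(a, b)] for a in t1) for b in t2)
    return (fwd + bwd) / (len(t1) + len(t2))


def filter_large_terms(
    ann: AnnotationSet,
    fraction: float = DEFAULT_LARGE_TERM_FRACTION,
    n_genes: int | None = None,
) -> tuple[AnnotationSet, set[str]]:
    """Drop terms annotating more than ``fraction`` of the species' genes.

    ``n_genes`` is the species' total gene count; when omitted the number of
    annotated genes is used, which overstates the threshold for sparsely
    annotated genomes.  Returns the filtered annotation set (genes with no
    terms left are removed) and the set of removed terms.
    """
    if n_genes is None:
        n_genes = len(ann.annotations)
    counts: dict[str, int] = {}
    for terms in ann.annotations.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    large = {t for t, c in counts.items() if n_genes and c > fraction * n_genes}
    filtered: dict[str, set[str]] = {}
    dropped_genes = []
    for g, terms in ann.annotations.items():
        kept = terms - large
        if kept:
            filtered[g] = kept
        else:
            dropped_genes.append(g)
    if dropped_genes:
        logger.info(
            "%d genes excluded: only annotated with large terms", len(dropped_genes)
        )
    evidence = {
        (g, t): codes
        for (g, t), codes in ann.evidence.items()
        if g in filtered and t in filtered[g]
    }
    return AnnotationSet(ann.species, filtered, evidence), large


def build_go_network(
    ann: AnnotationSet,
    dag: OntologyDAG,
    cutoff: float = 0.8,
    large_term_fraction: float = DEFAULT_LARGE_TERM_FRACTION,
    weights: dict[str, float] | None = None,
    n_genes: int | None = None,
):
    """Gene network connecting pairs with gene-level similarity >= ``cutoff``.

    Edge weights carry the raw similarity; this network is used for
    conservation comparisons only and is never folded into the integrated
    network.
    """
    from .edge_scoring import ScoredNetwork  # local import to avoid a cycle

    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must be in (0, 1]")
    filtered, _ = filter_large_terms(ann, large_term_fraction, n_genes)
    genes = sorted(filtered.annotations)
    sv = {
        t: s_values(t, dag, weights)
        for g in genes
        for t in filtered.annotations[g]
    }
    net = ScoredNetwork(species=ann.species, data_type="go")
    for i, g1 in enumerate(genes):
        t1 = filtered.annotations[g1]
        for g2 in genes[i + 1 :]:
            t2 = filtered.annotations[g2]
            sim = _gene_similarity_from_svalues(t1, t2, sv)
            if sim >= cutoff:
                net.add_edge(g1, g2, sim)
    return net


def go_based_modules(
    ann: AnnotationSet,
    dag: OntologyDAG,
    cutoff: float = 0.8,
    large_term_fraction: float = DEFAULT_LARGE_TERM_FRACTION,
    min_size: int = 3,
    weights: dict[str, float] | None = None,
    n_genes: int | None = None,
):
    """Annotation-derived modules: connected components of the GO network.

    Provides a clustering-free module definition for robustness comparisons.
    """
    from .clustering import ModulePartition

    net = build_go_network(ann, dag, cutoff, large_term_fraction, weights, n_genes)
    modules: dict[int, frozenset[str]] = {}
    unassigned: set[str] = set()
    comps = sorted(
        nx.connected_components(net.graph), key=lambda c: (-len(c), min(c))
    )
    for comp in comps:
        if len(comp) >= min_size:
            modules[len(modules)] = frozenset(comp)
        else:
            unassigned |= set(comp)
    return ModulePartition(
        species=ann.species,
        modules=modules,
        unassigned=unassigned,
        parameters={"method": "go_components", "cutoff": cutoff},
    )
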