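"""Wang semantic similarity: S-values, term/gene similarity, GO network."""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from modcons.go_semantics import (
    AnnotationSet,
    OntologyDAG,
    build_go_network,
    filter_large_terms,
    gene_similarity,
    s_values,
    term_similarity,
)


def brute_force_s_values(term, dag, weights):
    """Independent oracle: enumerate every child->parent path explicitly.

    S(t) is the maximum over all directed paths from ``term`` to ``t`` of the
    product of edge weights along the path.
    """
    out = {term: 1.0}
    for anc in dag.ancestors(term):
        best = 0.0
        for path in nx.all_simple_paths(dag.graph, term, anc):
            prod = 1.0
            for u, v in zip(path, path[1:]):
                rel = dag.graph.edges[u, v].get("relation", "is_a")
                prod *= weights[rel]
            best = max(best, prod)
        out[anc] = best
    return out


def brute_force_term_similarity(t1, t2, dag, weights):
    s1 = brute_force_s_values(t1, dag, weights)
    s2 = brute_force_s_values(t2, dag, weights)
    shared = s1.keys() & s2.keys()
    if not shared:
        return 0.0
    return sum(s1[t] + s2[t] for t in shared) / (sum(s1.values()) + sum(s2.values()))


def random_dag(rng, n_terms=10):
    """Random layered ontology with mixed is_a/part_of relations."""
    g = nx.DiGraph()
    names = [f"T{i}" for i in range(n_terms)]
    g.add_node(names[0])  # root
    for i in range(1, n_terms):
        n_parents = int(rng.integers(1, min(i, 3) + 1))
        parents = rng.choice(i, size=n_parents, replace=False)
        for p in parents:
            rel = "is_a" if rng.random() < 0.7 else "part_of"
            g.add_edge(names[i], names[int(p)], relation=rel)
    return OntologyDAG(graph=g, namespace="biological_process")


class TestSValues:
    def test_root_term_is_alone(self, chain_dag):
        assert s_values("p", chain_dag) == {"p": 1.0}

    def test_chain_single_multiplication(self, chain_dag):
        assert s_values("c", chain_dag) == {"c": 1.0, "p": pytest.approx(0.8)}

    def test_diamond_max_over_paths(self, diamond_dag):
        s = s_values("c", diamond_dag)
        assert s["r"] == pytest.approx(0.64)
        assert s["p1"] == s["p2"] == pytest.approx(0.8)

    def test_missing_term_raises(self, chain_dag):
        with pytest.raises(KeyError):
            s_values("nope", chain_dag)

    def test_part_of_uses_its_own_weight(self):
        g = nx.DiGraph()
        g.add_edge("c", "p", relation="part_of")
        dag = OntologyDAG(graph=g)
        assert s_values("c", dag)["p"] == pytest.approx(0.6)


class TestTermSimilarity:
    def test_self_similarity_is_exactly_one(self, diamond_dag):
        for t in diamond_dag.terms:
            assert term_similarity(t, t, diamond_dag) == 1.0

    def test_chain_value(self, chain_dag):
        # (0.8 + 1) / (1.8 + 1)
        assert term_similarity("c", "p", chain_dag) == pytest.approx(
            1.8 / 2.8, abs=1e-6
        )

    def test_disjoint_components_score_zero(self):
        g = nx.DiGraph()
        g.add_edge("a", "ra", relation="is_a")
        g.add_edge("b", "rb", relation="is_a")
        dag = OntologyDAG(graph=g)
        assert term_similarity("a", "b", dag) == 0.0

    def test_symmetry_and_bounds_on_random_dags(self):
        rng = np.random.default_rng(5)
        weights = {"is_a": 0.8, "part_of": 0.6}
        for _ in range(20):
            dag = random_dag(rng)
            terms = sorted(dag.terms)
            idx = rng.choice(len(terms), size=2, replace=False)
            t1, t2 = terms[int(idx[0])], terms[int(idx[1])]
            s12 = term_similarity(t1, t2, dag, weights)
            s21 = term_similarity(t2, t1, dag, weights)
            assert s12 == pytest.approx(s21)
            assert 0.0 <= s12 <= 1.0

    def test_agreement_with_brute_force_oracle(self):
        """100 random 10-term DAGs: dynamic programming == path enumeration."""
        rng = np.random.default_rng(12345)
        weights = {"is_a": 0.8, "part_of": 0.6}
        for _ in range(100):
            dag = random_dag(rng)
            terms = sorted(dag.terms)
            for t1, t2 in combinations(rng.choice(terms, 4, replace=False), 2):
                expected = brute_force_term_similarity(str(t1), str(t2), dag, weights)
                actual = term_similarity(str(t1), str(t2), dag, weights)
                assert actual == pytest.approx(expected, abs=1e-12)


class TestGeneSimilarity:
    def test_identical_annotation_sets(self, chain_dag):
        ann = AnnotationSet("A", {"g1": {"c", "p"}, "g2": {"c", "p"}})
        assert gene_similarity("g1", "g2", ann, chain_dag) == pytest.approx(1.0)

    def test_chain_single_best_match(self, chain_dag, toy_annotations):
        assert gene_similarity("g1", "g2", toy_annotations, chain_dag) == pytest.approx(
            1.8 / 2.8, abs=1e-6
        )

    def test_unannotated_gene_rejected(self, chain_dag):
        ann = AnnotationSet("A", {"g1": {"c"}})
        with pytest.raises(ValueError):
            gene_similarity("g1", "gX", ann, chain_dag)

    def test_shared_annotation_never_decreases_similarity(self, diamond_dag):
        rng = np.random.default_rng(9)
        terms = sorted(diamond_dag.terms)
        for _ in range(25):
            t1 = {str(t) for t in rng.choice(terms, int(rng.integers(1, 3)), replace=False)}
            t2 = {str(t) for t in rng.choice(terms, int(rng.integers(1, 3)), replace=False)}
            extra = str(terms[int(rng.integers(len(terms)))])
            ann1 = AnnotationSet("A", {"g1": set(t1), "g2": set(t2)})
            ann2 = AnnotationSet(
                "A", {"g1": t1 | {extra}, "g2": t2 | {extra}}
            )
            base = gene_similarity("g1", "g2", ann1, diamond_dag)
            boosted = gene_similarity("g1", "g2", ann2, diamond_dag)
            assert boosted >= base - 1e-12


class TestLargeTermFilterAndNetwork:
    def test_large_term_removed_everywhere(self):
        ann = AnnotationSet(
            "A",
            {f"g{i}": {"big"} | ({"small"} if i < 2 else set()) for i in range(10)},
        )
        filtered, removed = filter_large_terms(ann, fraction=0.05, n_genes=50)
        assert removed == {"big"}  # annotates 20% of a 50-gene genome
        assert filtered.genes == {"g0", "g1"}  # only carriers of 'small' survive

    def test_go_network_cutoff(self, chain_dag, toy_annotations):
        # g1={c}, g2={p}: similarity ~0.643 < 0.8 -> no edge; g3={c,p} vs g1
        net_high = build_go_network(
            toy_annotations, chain_dag, cutoff=0.8, n_genes=1000
        )
        assert not net_high.has_edge("g1", "g2")
        net_low = build_go_network(
            toy_annotations, chain_dag, cutoff=0.6, n_genes=1000
        )
        assert net_low.has_edge("g1", "g2")
        assert net_low.weight("g1", "g2") == pytest.approx(1.8 / 2.8, abs=1e-6)

    def test_identical_sets_edge_weight_one(self, chain_dag):
        ann = AnnotationSet("A", {"g1": {"c"}, "g2": {"c"}, "g3": {"p"}})
        net = build_go_network(ann, chain_dag, cutoff=0.8, n_genes=1000)
        assert net.weight("g1", "g2") == pytest.approx(1.0)

    def test_go_based_modules_are_network_components(self, chain_dag):
        from modcons.go_semantics import go_based_modules

        ann = AnnotationSet(
            "A",
            {
                "g1": {"c"}, "g2": {"c"}, "g3": {"c"},  # one tight component
                "h1": {"p"}, "h2": {"p"},  # below the size floor
            },
        )
        part = go_based_modules(ann, chain_dag, cutoff=0.9, min_size=3, n_genes=1000)
        assert list(map(set, part.modules.values())) == [{"g1", "g2", "g3"}]
        assert part.unassigned == {"h1", "h2"}

    def test_gene_with_only_large_term_excluded(self, chain_dag):
        ann = AnnotationSet(
            "A",
            {f"g{i}": {"c"} for i in range(3)} | {"gbig": {"p"}},
        )
        # p annotates 1 of 4 genes = 25% of a 4-gene genome -> large
        net = build_go_network(ann, chain_dag, cutoff=0.8, large_term_fraction=0.2)
        assert "gbig" not in net.graph.nodes
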