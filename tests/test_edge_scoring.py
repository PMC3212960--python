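"""Log-likelihood scoring: Spearman pairs, LLS arithmetic, network builders."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from modcons.edge_scoring import (
    CoannotationReference,
    UnscorableError,
    bin_pairs_by_rank,
    build_binary_network,
    build_coexpression_network,
    build_sequence_network,
    compute_lls,
    lls_bin_table,
    spearman_pairs,
)
from modcons.go_semantics import AnnotationSet
from modcons.io_formats import ExpressionMatrix, RawEdgeList


def expr_of(rows: dict[str, list[float]], species="A", experiment="e1"):
    df = pd.DataFrame(rows).T
    df.columns = [f"t{i}" for i in range(df.shape[1])]
    return ExpressionMatrix(species=species, values=df, experiment_id=experiment)


def reference_of(annotations: dict[str, set[str]], n_genes=1000):
    # a large genome denominator keeps toy terms below the large-term cutoff
    ann = AnnotationSet(species="A", annotations=annotations)
    return CoannotationReference(ann, n_genes=n_genes)


class TestSpearman:
    @pytest.mark.parametrize(
        "g2,expected",
        [
            ([2, 4, 6, 8], 1.0),
            ([4, 3, 2, 1], -1.0),
            ([1, 3, 2, 4], 0.8),  # 1 - 6*2/(4*15)
        ],
    )
    def test_rank_correlation_values(self, g2, expected):
        expr = expr_of({"g1": [1, 2, 3, 4], "g2": g2})
        pairs = dict(spearman_pairs(expr))
        assert pairs[("g1", "g2")] == pytest.approx(expected)

    def test_constant_profile_omitted(self):
        expr = expr_of({"g1": [1, 2, 3, 4], "g2": [5, 5, 5, 5]})
        assert spearman_pairs(expr) == []

    def test_pairwise_complete_overlap_floor(self):
        expr = expr_of(
            {
                "g1": [1, 2, 3, np.nan, np.nan],
                "g2": [2, 4, 6, 8, np.nan],
                "g3": [1, np.nan, np.nan, np.nan, 2],
            }
        )
        pairs = dict(spearman_pairs(expr, min_overlap=3))
        assert ("g1", "g2") in pairs  # 3 shared arrays
        assert ("g1", "g3") not in pairs  # only 1 shared array
        assert ("g2", "g3") not in pairs


class TestComputeLLS:
    def test_worked_example(self):
        # odds 50:50 in the bin vs 100:900 background -> ln 9
        assert compute_lls(100, 50, 1000, 100) == pytest.approx(
            math.log(9), abs=1e-9
        )

    def test_background_fraction_bin_scores_zero(self):
        assert compute_lls(100, 10, 1000, 100) == pytest.approx(0.0, abs=1e-12)

    def test_depleted_bin_negative(self):
        assert compute_lls(10, 1, 1000, 500) == pytest.approx(
            -math.log(9), abs=1e-9
        )

    @pytest.mark.parametrize("linked", [0, 10])
    def test_degenerate_bins_unscorable(self, linked):
        with pytest.raises(UnscorableError):
            compute_lls(10, linked, 1000, 100)

    def test_monotone_in_linked_fraction(self):
        values = [compute_lls(100, k, 10_000, 500) for k in range(1, 100)]
        assert all(b > a for a, b in zip(values, values[1:]))


class TestBinning:
    def test_ties_stay_in_lower_rank_bin(self):
        scored = [
            (("a", "b"), 0.9),
            (("a", "c"), 0.5),
            (("b", "c"), 0.5),
            (("c", "d"), 0.1),
        ]
        bins = bin_pairs_by_rank(scored, bin_size=2)
        assert [p for p, _ in bins[0]] == [("a", "b"), ("a", "c")]
        assert [p for p, _ in bins[1]] == [("b", "c"), ("c", "d")]

    def test_bin_table_orders_and_flags(self):
        ref = reference_of({"g1": {"t"}, "g2": {"t"}, "g3": {"u"}, "g4": {"u"}})
        scored = [
            (("g1", "g2"), 0.9),  # linked
            (("g1", "g3"), 0.6),  # not linked
            (("g2", "g3"), 0.3),
            (("g3", "g4"), 0.1),  # linked
        ]
        table = lls_bin_table(scored, ref, bin_size=2)
        assert len(table.bins) == 2
        assert table.background == (6, 2)
        # ascending SCC order in the stored table
        assert table.bins[0].upper <= table.bins[1].lower + 1e-12


class TestCoexpressionNetwork:
    def test_max_rule_across_experiments(self):
        ref = reference_of(
            {"g1": {"t"}, "g2": {"t"}, "g3": {"u"}, "g4": {"u"}, "g5": {"v"}}
        )
        e1 = expr_of({"g1": [1, 2, 3, 4], "g2": [1, 2, 4, 3], "g3": [4, 3, 2, 1]})
        e2 = expr_of(
            {"g1": [1, 2, 3, 4], "g2": [1, 2, 3, 4], "g3": [2, 1, 4, 3]},
            experiment="e2",
        )
        net1 = build_coexpression_network([e1], ref, bin_size=2)
        net2 = build_coexpression_network([e2], ref, bin_size=2)
        both = build_coexpression_network([e1, e2], ref, bin_size=2)
        assert net1.has_edge("g1", "g2") and net2.has_edge("g1", "g2")
        assert both.weight("g1", "g2") == pytest.approx(
            max(net1.weight("g1", "g2"), net2.weight("g1", "g2"))
        )

    def test_experiment_order_invariance(self, small_scenario):
        ref = small_scenario.reference("A")
        exps = [
            small_scenario.expression["A"][0],
            # a second, noisier experiment from the same modules
        ]
        net_fwd = build_coexpression_network(exps, ref, bin_size=200)
        net_rev = build_coexpression_network(list(reversed(exps)), ref, bin_size=200)
        assert net_fwd.edge_set() == net_rev.edge_set()
        for a, b, w in net_fwd.edges():
            assert net_rev.weight(a, b) == pytest.approx(w)

    def test_all_nonpositive_bins_gives_empty_network(self):
        # annotations uncorrelated with expression: a single bin at background
        ref = reference_of({"g1": {"t"}, "g2": {"u"}, "g3": {"t"}, "g4": {"u"}})
        expr = expr_of(
            {
                "g1": [1, 2, 3, 4],
                "g2": [1, 2, 4, 3],
                "g3": [4, 3, 1, 2],
                "g4": [3, 4, 1, 2],
            }
        )
        net = build_coexpression_network([expr], ref, bin_size=6)
        assert net.n_edges == 0

    def test_planted_coexpression_recovery(self, small_scenario):
        """Expression-derived network recovers planted co-expressed pairs.

        Module members share a latent profile, so within-module pairs rank in
        the top correlation bins, score positive LLS, and at least 90% of the
        planted co-expression pairs are recovered.
        """
        sc = small_scenario
        ref = sc.reference("A")
        net = build_coexpression_network(sc.expression["A"], ref, bin_size=500)
        planted = {
            (a, b)
            for (a, b), lab in sc.ground_truth.edge_labels.items()
            if lab["kind"] == "within"
        }
        recovered = net.edge_set()
        assert len(recovered & planted) / len(planted) >= 0.9


class TestBinaryAndSequence:
    def test_binary_weight_equals_compute_lls_exactly(self):
        ref = reference_of(
            {"g1": {"t"}, "g2": {"t"}, "g3": {"u"}, "g4": {"u"}, "g5": {"w"}}
        )
        raw = RawEdgeList(
            species="A",
            data_type="ppi",
            records=[("g1", "g2", None), ("g1", "g3", None)],
        )
        net = build_binary_network(raw, ref)
        known, linked = ref.count_pairs(raw.pairs())
        expected = compute_lls(known, linked, *ref.background)
        for _, _, w in net.edges():
            assert w == expected

    def test_background_level_edge_set_dropped(self):
        # linked fraction of the edge set == background linked fraction -> LLS 0
        ref = reference_of({"g1": {"t"}, "g2": {"t"}, "g3": {"u"}, "g4": {"v"}})
        # background: 6 pairs, 1 linked; edge set: 6 pairs, 1 linked
        raw = RawEdgeList(
            species="A",
            data_type="ppi",
            records=[
                ("g1", "g2", None),
                ("g1", "g3", None),
                ("g1", "g4", None),
                ("g2", "g3", None),
                ("g2", "g4", None),
                ("g3", "g4", None),
            ],
        )
        net = build_binary_network(raw, ref)
        assert net.n_edges == 0

    def test_no_annotated_pairs_errors(self):
        ref = reference_of({"g1": {"t"}, "g2": {"u"}})
        raw = RawEdgeList(
            species="A", data_type="ppi", records=[("x", "y", None)]
        )
        with pytest.raises(UnscorableError):
            build_binary_network(raw, ref)

    @pytest.mark.parametrize(
        "evalue,kept",
        [
            (1e-30, True),  # 1e-30 < 1e-25/5000 = 2e-29
            (1e-28, False),  # 1e-28 >= 2e-29
        ],
    )
    def test_sequence_evalue_threshold(self, evalue, kept):
        ref = reference_of({"g1": {"t"}, "g2": {"t"}, "g3": {"u"}, "g4": {"u"}})
        hits = RawEdgeList(
            species="A",
            data_type="blast_hit",
            records=[("g1", "g2", evalue), ("g2", "g1", evalue), ("g3", "g4", 1e-40)],
        )
        net = build_sequence_network(hits, n_genes=5000, reference=ref)
        assert net.has_edge("g1", "g2") is kept

    def test_self_hits_ignored(self):
        ref = reference_of({"g1": {"t"}, "g2": {"t"}, "g3": {"u"}, "g4": {"u"}})
        hits = RawEdgeList(
            species="A",
            data_type="blast_hit",
            records=[("g1", "g1", 0.0), ("g1", "g2", 1e-40), ("g3", "g4", 1e-40)],
        )
        net = build_sequence_network(hits, n_genes=100, reference=ref)
        assert not net.has_edge("g1", "g1")
        assert net.has_edge("g1", "g2")
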