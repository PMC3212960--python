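"""Conservation statistics: edge classes, direct/extended rates, reports."""

from __future__ import annotations

import pytest

from modcons.clustering import ModulePartition
from modcons.conservation import (
    classify_edges,
    conservation_report,
    degree_binned_conservation,
    direct_conserved,
    extended_conserved,
    geneset_conservation,
)
from modcons.orthology import OrthologyMap, identity_map

from conftest import make_integrated


def part(species, modules, unassigned=()):
    return ModulePartition(
        species,
        {i: frozenset(m) for i, m in enumerate(modules)},
        set(unassigned),
    )


@pytest.fixture
def toy_comparison():
    """6-node query, identity-mapped reference with half the edges."""
    net_a = make_integrated(
        "A",
        [
            ("a", "b", 1.0),  # within module 0, image edge present
            ("a", "c", 1.0),  # within module 0, image edge absent
            ("d", "e", 1.0),  # within module 1, image present
            ("c", "d", 1.0),  # between modules, image absent
        ],
    )
    net_b = make_integrated("B", [("a", "b", 1.0), ("d", "e", 1.0), ("x", "y", 1.0)])
    part_a = part("A", [{"a", "b", "c"}, {"d", "e", "f"}])
    part_b = part("B", [{"a", "b", "c"}, {"d", "e", "f"}])
    omap = identity_map(["a", "b", "c", "d", "e", "f"], "A", "B")
    return net_a, net_b, part_a, part_b, omap


class TestClassify:
    def test_wmi_bmi_unclassified(self):
        net = make_integrated(
            "A", [("a", "b", 1), ("b", "c", 1), ("a", "z", 1)]
        )
        p = part("A", [{"a", "b", "e"}, {"c", "d", "f"}], unassigned={"z"})
        labels = classify_edges(net, p)
        assert labels[("a", "b")] == "WMI"
        assert labels[("b", "c")] == "BMI"
        assert labels[("a", "z")] == "unclassified"


class TestDirectAndExtended:
    def test_direct_present_and_absent(self, toy_comparison):
        net_a, net_b, _, _, omap = toy_comparison
        assert direct_conserved(("a", "b"), omap, net_b)
        assert not direct_conserved(("a", "c"), omap, net_b)

    def test_many_to_many_any_combination_counts(self):
        net_b = make_integrated("B", [("x2", "y1", 1.0)])
        omap = OrthologyMap(
            "A",
            "B",
            pairs={("a", "x1"), ("a", "x2"), ("b", "y1"), ("b", "y2")},
            mode="many_to_many",
        )
        assert direct_conserved(("a", "b"), omap, net_b)

    def test_extended_needs_shared_reference_module(self, toy_comparison):
        _, _, _, part_b, omap = toy_comparison
        assert extended_conserved(("a", "c"), omap, part_b)  # same module in B
        assert not extended_conserved(("c", "d"), omap, part_b)  # split in B

    def test_unassigned_images_not_extended(self, toy_comparison):
        _, _, _, _, omap = toy_comparison
        part_b = ModulePartition("B", {}, {"a", "b", "c", "d", "e", "f"})
        assert not extended_conserved(("a", "c"), omap, part_b)


class TestReport:
    def test_toy_counts_and_rates(self, toy_comparison):
        net_a, net_b, part_a, part_b, omap = toy_comparison
        rep = conservation_report(net_a, net_b, omap, part_a, part_b)
        assert rep.n_comparable_edges == 4
        assert rep.n_wmi == 3 and rep.n_bmi == 1
        assert rep.rate("baseline_direct") == pytest.approx(0.5)
        assert rep.rate("wmi_direct") == pytest.approx(2 / 3)
        assert rep.rate("bmi_direct") == 0.0
        # a-c is extended-conserved (same module in B)
        assert rep.rate("wmi_extended") == pytest.approx(1.0)
        assert rep.counts["baseline_extended"] == 3

    def test_extended_at_least_direct_everywhere(self, toy_comparison):
        net_a, net_b, part_a, part_b, omap = toy_comparison
        rep = conservation_report(net_a, net_b, omap, part_a, part_b)
        for cls in ("baseline", "wmi", "bmi"):
            assert rep.counts[f"{cls}_extended"] >= rep.counts[f"{cls}_direct"]

    def test_self_comparison_rates_all_one(self, small_scenario):
        net = small_scenario.integrated("A")
        from modcons import clustering

        p = clustering.mcl(net)
        omap = identity_map([g for g in net.graph.nodes], "A", "A")
        rep = conservation_report(net, net, omap, p, p)
        assert rep.rate("baseline_direct") == 1.0
        for key in ("wmi_direct", "bmi_direct"):
            if rep.counts[key] or rep._denominator(key):
                assert rep.rate(key) == 1.0

    def test_undefined_rate_is_none_not_zero(self):
        net_a = make_integrated("A", [("a", "b", 1.0)])
        net_b = make_integrated("B", [("a", "b", 1.0)])
        p_a = part("A", [{"a", "b", "c"}])
        p_b = part("B", [{"a", "b", "c"}])
        omap = identity_map(["a", "b", "c"], "A", "B")
        rep = conservation_report(net_a, net_b, omap, p_a, p_b)
        assert rep.n_bmi == 0
        assert rep.rate("bmi_direct") is None

    def test_hub_exclusion_drops_incident_edges(self):
        center = "h"
        leaves = [f"l{i}" for i in range(5)]
        net_a = make_integrated(
            "A", [(center, l, 1.0) for l in leaves] + [("l0", "l1", 1.0)]
        )
        net_b = make_integrated("B", [(center, "l0", 1.0), ("l0", "l1", 1.0)])
        p = part("A", [set([center] + leaves)])
        p_b = part("B", [set([center] + leaves)])
        omap = identity_map([center] + leaves, "A", "B")
        rep = conservation_report(
            net_a, net_b, omap, p, p_b, hub_exclusion=5
        )
        # all hub-incident edges dropped; only l0-l1 remains, and it is conserved
        assert rep.n_comparable_edges == 1
        assert rep.rate("baseline_direct") == 1.0

    def test_unmapped_endpoints_excluded_from_denominator(self):
        net_a = make_integrated("A", [("a", "b", 1.0), ("a", "u", 1.0)])
        net_b = make_integrated("B", [("a", "b", 1.0)])
        p_a = part("A", [{"a", "b", "u"}])
        p_b = part("B", [{"a", "b", "u"}])
        omap = OrthologyMap("A", "B", pairs={("a", "a"), ("b", "b")})
        rep = conservation_report(net_a, net_b, omap, p_a, p_b)
        assert rep.n_comparable_edges == 1


class TestDegreeBinsAndGenesets:
    def test_star_edges_count_in_both_bins(self):
        center = "h"
        leaves = [f"l{i}" for i in range(10)]
        net_a = make_integrated("A", [(center, l, 1.0) for l in leaves])
        net_b = make_integrated("B", [(center, leaves[0], 1.0)])
        omap = identity_map([center] + leaves, "A", "B")
        out = degree_binned_conservation(net_a, net_b, omap, bin_edges=[0, 5])
        low, high = out
        assert low["n_edges"] == 10  # every edge has a degree-1 leaf
        assert high["n_edges"] == 10  # and the degree-10 center
        assert high["rate"] == pytest.approx(0.1)

    def test_uniform_degree_occupies_single_bin(self):
        net = make_integrated("A", [("a", "b", 1), ("b", "c", 1), ("c", "a", 1)])
        omap = identity_map(["a", "b", "c"], "A", "B")
        out = degree_binned_conservation(net, net, omap, bin_edges=[0, 10])
        assert out[0]["n_edges"] == 3
        assert out[1]["n_edges"] == 0
        assert out[1]["rate"] is None

    def test_geneset_full_set_equals_baseline(self, toy_comparison):
        net_a, net_b, part_a, part_b, omap = toy_comparison
        rep = conservation_report(net_a, net_b, omap, part_a, part_b)
        gs = geneset_conservation(
            net_a, net_b, omap, set("abcdef")
        )
        assert gs["rate"] == rep.rate("baseline_direct")

    def test_geneset_empty_set_undefined(self, toy_comparison):
        net_a, net_b, _, _, omap = toy_comparison
        gs = geneset_conservation(net_a, net_b, omap, set())
        assert gs["rate"] is None

    def test_geneset_half_conserved(self, toy_comparison):
        net_a, net_b, _, _, omap = toy_comparison
        gs = geneset_conservation(net_a, net_b, omap, {"a"})
        # edges touching a: (a,b) conserved, (a,c) not
        assert gs["rate"] == pytest.approx(0.5)
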