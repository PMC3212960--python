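"""Directed cross-species edge-conservation statistics.

For a query species A and reference species B, every edge of A whose two
endpoints both have orthologs in B is *comparable*.  A comparable edge is

* **directly conserved** when some pair of ortholog images is itself an edge
  of the B network;
* **extended-conserved** when it is directly conserved, or some pair of
  ortholog images lies inside one retained module of B — capturing
  interactions whose effect is mediated through the module even if the
  specific edge was lost or never measured.

Comparable edges are classified by the query partition into within-module
interactions (WMI: both endpoints in the same retained module), between-
module interactions (BMI: endpoints in two different retained modules) and
unclassified edges (an endpoint outside any retained module).  Unclassified
edges count toward the baseline rates only.  Rates with an empty denominator
are reported as undefined (None), never as zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

from .clustering import ModulePartition
from .orthology import OrthologyMap

logger = logging.getLogger(__name__)

WMI = "WMI"
BMI = "BMI"
UNCLASSIFIED = "unclassified"

#: default hub-exclusion degree cutoff used in the hub sensitivity analysis
DEFAULT_HUB_DEGREE = 300


def _rate(count: int, denom: int) -> float | None:
    return count / denom if denom else None


@dataclass
class ConservationReport:
    """Counts and rates for one directed species comparison."""

    query_species: str
    reference_species: str
    data_type: str
    n_comparable_edges: int
    n_wmi: int
    n_bmi: int
    n_unclassified: int
    counts: dict[str, int] = field(default_factory=dict)
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_wmi + self.n_bmi + self.n_unclassified != self.n_comparable_edges:
            raise ValueError("edge class counts do not sum to comparable edges")

    def _denominator(self, key: str) -> int:
        if key.startswith("baseline"):
            return self.n_comparable_edges
        if key.startswith("wmi"):
            return self.n_wmi
        if key.startswith("bmi"):
            return self.n_bmi
        raise KeyError(key)

    def rate(self, key: str) -> float | None:
        """Conservation rate for a statistic key, or None when undefined."""
        return _rate(self.counts[key], self._denominator(key))

    @property
    def rates(self) -> dict[str, float | None]:
        return {k: self.rate(k) for k in self.counts}

    def to_dict(self) -> dict:
        return {
            "query_species": self.query_species,
            "reference_species": self.reference_species,
            "data_type": self.data_type,
            "n_comparable_edges": self.n_comparable_edges,
            "n_wmi": self.n_wmi,
            "n_bmi": self.n_bmi,
            "n_unclassified": self.n_unclassified,
            "counts": dict(self.counts),
            "rates": self.rates,
            "options": dict(self.options),
        }


def classify_edges(net_a, part_a: ModulePartition) -> dict[tuple[str, str], str]:
    """Label each edge WMI / BMI / unclassified by query module membership."""
    if part_a.species and net_a.species and part_a.species != net_a.species:
        raise ValueError("partition and network species differ")
    labels: dict[tuple[str, str], str] = {}
    for row in net_a.edges():
        a, b = row[0], row[1]
        ma, mb = part_a.module_of(a), part_a.module_of(b)
        if ma is None or mb is None:
            labels[(a, b)] = UNCLASSIFIED
        elif ma == mb:
            labels[(a, b)] = WMI
        else:
            labels[(a, b)] = BMI
    return labels


def direct_conserved(
    edge: tuple[str, str], omap: OrthologyMap, net_b
) -> bool:
    """Is some pair of ortholog images of this edge an edge of the reference?"""
    imgs_a = omap.image(edge[0])
    imgs_b = omap.image(edge[1])
    if not imgs_a or not imgs_b:
        raise ValueError(f"edge {edge} has an orthology-unmapped endpoint")
    return any(
        x != y and net_b.has_edge(x, y) for x, y in product(imgs_a, imgs_b)
    )


def extended_conserved(
    edge: tuple[str, str], omap: OrthologyMap, part_b: ModulePartition
) -> bool:
    """Do some ortholog images of the endpoints share a retained module of B?"""
    imgs_a = omap.image(edge[0])
    imgs_b = omap.image(edge[1])
    for x, y in product(imgs_a, imgs_b):
        if x == y:
            continue
        mx = part_b.module_of(x)
        if mx is not None and mx == part_b.module_of(y):
            return True
    return False


def conservation_report(
    net_a,
    net_b,
    omap: OrthologyMap,
    part_a: ModulePartition,
    part_b: ModulePartition,
    hub_exclusion: int | None = None,
    degree_network=None,
    data_type: str = "integrated",
) -> ConservationReport:
    """Full directed conservation report of A's edges against B.

    ``hub_exclusion`` drops every comparable edge incident to a node whose
    degree meets the cutoff; degrees are measured on ``degree_network`` (the
    query species' integrated network) when given, else on ``net_a`` itself.
    """
    deg_net = degree_network if degree_network is not None else net_a
    labels = classify_edges(net_a, part_a)
    counts = {
        "baseline_direct": 0,
        "baseline_extended": 0,
        "wmi_direct": 0,
        "wmi_extended": 0,
        "bmi_direct": 0,
        "bmi_extended": 0,
    }
    n_by_class = {WMI: 0, BMI: 0, UNCLASSIFIED: 0}
    mapped = omap.mapped_a
    for (a, b), label in labels.items():
        if a not in mapped or b not in mapped:
            continue
        if hub_exclusion is not None and (
            deg_net.degree(a) >= hub_exclusion or deg_net.degree(b) >= hub_exclusion
        ):
            continue
        n_by_class[label] += 1
        direct = direct_conserved((a, b), omap, net_b)
        extended = direct or extended_conserved((a, b), omap, part_b)
        counts["baseline_direct"] += direct
        counts["baseline_extended"] += extended
        if label == WMI:
            counts["wmi_direct"] += direct
            counts["wmi_extended"] += extended
        elif label == BMI:
            counts["bmi_direct"] += direct
            counts["bmi_extended"] += extended
    report = ConservationReport(
        query_species=net_a.species,
        reference_species=net_b.species,
        data_type=data_type,
        n_comparable_edges=sum(n_by_class.values()),
        n_wmi=n_by_class[WMI],
        n_bmi=n_by_class[BMI],
        n_unclassified=n_by_class[UNCLASSIFIED],
        counts=counts,
        options={
            "hub_exclusion_degree": hub_exclusion,
            "mapping_mode": omap.mode,
        },
    )
    for key in ("wmi", "bmi", "baseline"):
        if report.counts[f"{key}_extended"] < report.counts[f"{key}_direct"]:
            raise AssertionError("extended count fell below direct count")
    return report


def degree_binned_conservation(
    net_a, net_b, omap: OrthologyMap, bin_edges: list[float], degree_network=None
) -> list[dict]:
    """Direct conservation rate per degree bin.

    An edge contributes to bin k when at least one endpoint's degree falls in
    [bin_edges[k], bin_edges[k+1]); the last bin is open-ended.  An edge whose
    endpoints fall in two different bins counts in both.
    """
    if any(b >= c for b, c in zip(bin_edges, bin_edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    deg_net = degree_network if degree_network is not None else net_a
    bounds = list(bin_edges) + [float("inf")]
    mapped = omap.mapped_a

    def bin_of(degree: float) -> int | None:
        for k in range(len(bounds) - 1):
            if bounds[k] <= degree < bounds[k + 1]:
                return k
        return None

    totals = [0] * (len(bounds) - 1)
    conserved = [0] * (len(bounds) - 1)
    for row in net_a.edges():
        a, b = row[0], row[1]
        if a not in mapped or b not in mapped:
            continue
        direct = direct_conserved((a, b), omap, net_b)
        bins = {bin_of(deg_net.degree(a)), bin_of(deg_net.degree(b))} - {None}
        for k in bins:
            totals[k] += 1
            conserved[k] += direct
    return [
        {
            "lower": bounds[k],
            "upper": bounds[k + 1],
            "n_edges": totals[k],
            "n_conserved": conserved[k],
            "rate": _rate(conserved[k], totals[k]),
        }
        for k in range(len(bounds) - 1)
    ]


def geneset_conservation(
    net_a, net_b, omap: OrthologyMap, genes: set[str]
) -> dict:
    """Direct conservation of comparable edges touching a gene set.

    Mirrors the per-molecular-function analysis: edges with at least one
    endpoint in ``genes`` versus the rest of the genome.
    """
    mapped = omap.mapped_a
    total = conserved = 0
    for row in net_a.edges():
        a, b = row[0], row[1]
        if a not in mapped or b not in mapped:
            continue
        if a not in genes and b not in genes:
            continue
        total += 1
        conserved += direct_conserved((a, b), omap, net_b)
    return {"n_edges": total, "n_conserved": conserved, "rate": _rate(conserved, total)}
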