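"""End-to-end composition of the analysis stages on a generated scenario.

Thin orchestration only: score evidence into networks, integrate, cluster
with MCL, then compute conservation statistics and null distributions for a
directed species comparison.  All scientific content lives in the stage
modules; this module just wires them together so tests, scripts and the
command line share one code path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import clustering
from .clustering import ModulePartition
from .conservation import ConservationReport, conservation_report
from .integration import DEFAULT_INTEGRATED_TAGS, IntegratedNetwork, integrate
from .randomization import NullDistributionResult, null_distribution
from .synthetic_data import Scenario

logger = logging.getLogger(__name__)


@dataclass
class ComparisonResult:
    """Everything the directed comparison A -> B produced."""

    net_a: IntegratedNetwork
    net_b: IntegratedNetwork
    part_a: ModulePartition
    part_b: ModulePartition
    report: ConservationReport
    null: NullDistributionResult | None = None
    evidence_nets_a: list = field(default_factory=list)


def run_comparison(
    scenario: Scenario,
    query: str = "A",
    reference: str = "B",
    include=DEFAULT_INTEGRATED_TAGS,
    mcl_kwargs: dict | None = None,
    hub_exclusion: int | None = None,
    null_method: str | None = None,
    n_null_replicates: int = 100,
    null_seed: int = 0,
) -> ComparisonResult:
    """Full directed conservation analysis of a synthetic scenario.

    Both species' evidence networks are LLS-scored and integrated, each
    integrated network is clustered with MCL, and the query's edges are
    scored for conservation against the reference.  When ``null_method`` is
    given the same procedure is repeated on randomized query networks.
    """
    mcl_kwargs = mcl_kwargs or {}
    omap = scenario.orthology
    if query == "B":
        omap = omap.reversed()
    nets_q = scenario.scored_networks(query)
    nets_r = scenario.scored_networks(reference)
    net_q = integrate(nets_q, include=include)
    net_r = integrate(nets_r, include=include)
    part_q = clustering.mcl(net_q, **mcl_kwargs)
    part_r = clustering.mcl(net_r, **mcl_kwargs)
    report = conservation_report(
        net_q, net_r, omap, part_q, part_r, hub_exclusion=hub_exclusion
    )
    null = None
    if null_method is not None:
        null = null_distribution(
            nets_q,
            net_r,
            omap,
            part_r,
            method=null_method,
            n_replicates=n_null_replicates,
            seed=null_seed,
            include=include,
            mcl_kwargs=mcl_kwargs,
            hub_exclusion=hub_exclusion,
        )
    return ComparisonResult(
        net_a=net_q,
        net_b=net_r,
        part_a=part_q,
        part_b=part_r,
        report=report,
        null=null,
        evidence_nets_a=nets_q,
    )
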