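"""Null models and empirical significance for module-conservation statistics.

Two randomizations are applied to the *query* species only; the reference
networks and modules stay fixed:

* **edge switching** — repeated double-edge swaps (a-b, c-d -> a-d, c-b)
  that preserve every node's degree exactly, each replacement edge carrying
  the weight of the original edge it replaces;
* **node label shuffling** — a random bijective relabelling, preserving the
  topology (and hence degree distribution and diameter) exactly.

Each evidence network is randomized separately, the randomized networks are
re-integrated, the combined network is re-clustered with MCL, and the full
conservation report is recomputed against the real reference.  Empirical
p-values use an add-one rule, p = (1 + #{null >= observed}) / (n + 1), so a
statistic exceeding every null replicate at n replicates reports p = 1/(n+1)
rather than zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import clustering
from .conservation import ConservationReport, conservation_report
from .integration import DEFAULT_INTEGRATED_TAGS, integrate
from .orthology import OrthologyMap

logger = logging.getLogger(__name__)

DEFAULT_SWAP_FACTOR = 10  # swap attempts per edge


@dataclass
class RandomizationSummary:
    statistic: str
    observed: float
    null_mean: float
    null_sd: float
    p_value: float
    n_replicates: int
    seed: int
    tail: str = "greater"


def empirical_p(observed: float, null_values, tail: str = "greater") -> float:
    """Add-one empirical p-value; always in (0, 1]."""
    null_values = list(null_values)
    if tail == "greater":
        extreme = sum(1 for v in null_values if v >= observed)
    elif tail == "less":
        extreme = sum(1 for v in null_values if v <= observed)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (1 + extreme) / (len(null_values) + 1)


def edge_switch(net, seed: int, n_swaps: int | None = None):
    """Degree-preserving randomization by double-edge swaps.

    ``n_swaps`` counts attempted swaps (default 10 per edge).  Swaps creating
    self-edges or multi-edges are rejected.  Returns a network of the same
    type; on graphs too constrained to swap the input is returned unchanged
    (with a warning).
    """
    rows = list(net.edges())
    m = len(rows)
    if m < 2:
        logger.warning("network too small to switch edges; returned unchanged")
        return net
    if n_swaps is None:
        n_swaps = DEFAULT_SWAP_FACTOR * m
    # edge list as mutable endpoint arrays; extra columns (weight/provenance)
    # travel with the edge slot, so replacement edges inherit the weight of
    # the edge they replace
    ends = [[r[0], r[1]] for r in rows]
    extras = [r[2:] for r in rows]
    present = {frozenset(e) for e in ends}
    rng = np.random.default_rng(seed)
    accepted = 0
    pick = rng.integers(0, m, size=(n_swaps, 2))
    flip = rng.random(n_swaps) < 0.5
    for t in range(n_swaps):
        i, j = int(pick[t, 0]), int(pick[t, 1])
        if i == j:
            continue
        a, b = ends[i]
        c, d = ends[j]
        if flip[t]:
            c, d = d, c
        # proposed: a-d and c-b
        if a == d or c == b:
            continue
        e1, e2 = frozenset((a, d)), frozenset((c, b))
        if e1 in present or e2 in present or e1 == e2:
            continue
        present.discard(frozenset((a, b)))
        present.discard(frozenset((c, d)))
        present.add(e1)
        present.add(e2)
        ends[i] = [a, d]
        ends[j] = [c, b]
        accepted += 1
    if accepted == 0:
        logger.warning("no legal edge swaps found; returned input unchanged")
        return net
    if hasattr(net, "data_type"):
        out = type(net)(species=net.species, data_type=net.data_type)
    else:
        out = type(net)(species=net.species)
    for (a, b), extra in zip(ends, extras):
        out.add_edge(a, b, *extra)
    return out


def node_label_shuffle(net, seed: int):
    """Randomly permute node labels; topology is untouched."""
    nodes = sorted(net.graph.nodes)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(nodes))
    mapping = {nodes[i]: nodes[int(perm[i])] for i in range(len(nodes))}
    if hasattr(net, "data_type"):
        out = type(net)(species=net.species, data_type=net.data_type)
    else:
        out = type(net)(species=net.species)
    for row in net.edges():
        out.add_edge(mapping[row[0]], mapping[row[1]], *row[2:])
    return out


#: conservation-report statistics summarised by default
DEFAULT_STATISTICS = (
    "baseline_direct",
    "wmi_direct",
    "bmi_direct",
    "wmi_extended",
    "bmi_extended",
    "wmi_minus_bmi",
)


def _extract(report: ConservationReport, statistic: str) -> float | None:
    if statistic == "wmi_minus_bmi":
        w, b = report.rate("wmi_direct"), report.rate("bmi_direct")
        return None if w is None or b is None else w - b
    return report.rate(statistic)


@dataclass
class NullDistributionResult:
    """Observed conservation report, null replicates and per-statistic summaries."""

    observed: ConservationReport
    replicates: list[ConservationReport]
    summaries: dict[str, RandomizationSummary]
    n_failed: int = 0
    replicate_seeds: list[int] = field(default_factory=list)


def null_distribution(
    evidence_nets_a: list,
    net_b,
    omap: OrthologyMap,
    part_b,
    method: str = "edge_switch",
    n_replicates: int = 100,
    seed: int = 0,
    include: frozenset[str] = DEFAULT_INTEGRATED_TAGS,
    statistics=DEFAULT_STATISTICS,
    tails: dict[str, str] | None = None,
    swap_factor: int = DEFAULT_SWAP_FACTOR,
    mcl_kwargs: dict | None = None,
    hub_exclusion: int | None = None,
) -> NullDistributionResult:
    """Empirical null for conservation statistics of one directed comparison.

    Per replicate: each evidence network of the query species is randomized,
    the randomized networks are aggregated into a combined network, MCL is
    re-run on it, and the conservation report is computed against the real
    reference network and modules.  Replicates whose report lacks a
    statistic (undefined rate) are excluded from that statistic's summary;
    replicates that fail outright are logged and dropped.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if method not in ("edge_switch", "node_label"):
        raise ValueError(f"unknown randomization method {method!r}")
    mcl_kwargs = mcl_kwargs or {}
    tails = tails or {}

    real_integrated = integrate(evidence_nets_a, include=include)
    real_part = clustering.mcl(real_integrated, **mcl_kwargs)
    observed = conservation_report(
        real_integrated, net_b, omap, real_part, part_b, hub_exclusion=hub_exclusion
    )

    rng = np.random.default_rng(seed)
    # one sub-seed per (replicate, evidence network), drawn up front so the
    # stream is independent of per-replicate control flow
    max_seed = 2**31 - 1
    replicate_seeds = [int(s) for s in rng.integers(0, max_seed, size=n_replicates)]

    replicates: list[ConservationReport] = []
    n_failed = 0
    for rep, rep_seed in enumerate(replicate_seeds):
        sub_rng = np.random.default_rng(rep_seed)
        try:
            randomized = []
            for net in evidence_nets_a:
                s = int(sub_rng.integers(0, max_seed))
                if method == "edge_switch":
                    randomized.append(
                        edge_switch(net, seed=s, n_swaps=swap_factor * net.n_edges)
                    )
                else:
                    randomized.append(node_label_shuffle(net, seed=s))
            combined = integrate(randomized, include=include)
            part_rand = clustering.mcl(combined, **mcl_kwargs)
            rep_report = conservation_report(
                combined, net_b, omap, part_rand, part_b, hub_exclusion=hub_exclusion
            )
            replicates.append(rep_report)
        except Exception:  # noqa: BLE001 - replicate failures are tolerated
            n_failed += 1
            logger.exception("null replicate %d failed; excluded", rep)
    summaries: dict[str, RandomizationSummary] = {}
    for stat in statistics:
        obs = _extract(observed, stat)
        nulls = [v for r in replicates if (v := _extract(r, stat)) is not None]
        if obs is None or not nulls:
            logger.warning("statistic %s undefined; no summary", stat)
            continue
        tail = tails.get(stat, "greater")
        summaries[stat] = RandomizationSummary(
            statistic=stat,
            observed=obs,
            null_mean=float(np.mean(nulls)),
            null_sd=float(np.std(nulls)),
            p_value=empirical_p(obs, nulls, tail=tail),
            n_replicates=len(nulls),
            seed=seed,
            tail=tail,
        )
    return NullDistributionResult(
        observed=observed,
        replicates=replicates,
        summaries=summaries,
        n_failed=n_failed,
        replicate_seeds=replicate_seeds,
    )
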