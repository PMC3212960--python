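"""Matching modules across species by hypergeometric overlap.

An A-module and a B-module match when, mapping the A-module's members into B
through the orthology, the overlap with the B-module is larger than expected
by chance in *both* directions.  The overlap p-value is the upper tail of the
hypergeometric distribution over the universe of ortholog pairs whose two
genes each sit in a retained module of their species.  Raw p-values are
Bonferroni-corrected by the number of module pairs tested and a pair of
modules is declared matching when both corrected p-values fall below the
significance cutoff (reciprocal significance).

The same one-directional machinery matches modules of a single species
against named gene sets such as experimentally defined protein complexes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy.stats import hypergeom

from .clustering import ModulePartition
from .orthology import OrthologyMap

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


def hypergeom_overlap_p(overlap: int, size1: int, size2: int, universe: int) -> float:
    """Upper-tail hypergeometric probability P(X >= overlap).

    The universe holds ``size1`` marked elements; ``size2`` are drawn without
    replacement; ``overlap`` marked elements are observed among the draws.
    """
    if not (0 <= overlap <= min(size1, size2) <= universe):
        raise ValueError(
            f"impossible configuration: overlap={overlap}, sizes=({size1},{size2}), "
            f"universe={universe}"
        )
    if size1 + size2 - overlap > universe:
        raise ValueError("sets larger than the universe allows")
    return float(hypergeom.sf(overlap - 1, universe, size1, size2))


@dataclass
class ModuleMatch:
    module_a: int
    size_a: int
    module_b: int
    size_b: int
    overlap: int
    universe: int
    p_a_to_b: float
    p_b_to_a: float
    corrected_a_to_b: float
    corrected_b_to_a: float
    reciprocal_significant: bool

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _bonferroni_factor(m_a: int, m_b: int, correction: str) -> int:
    if correction == "product":
        return m_a * m_b
    if correction == "sum":
        return m_a + m_b
    raise ValueError(f"unknown correction {correction!r}")


def match_partitions(
    part_a: ModulePartition,
    part_b: ModulePartition,
    omap: OrthologyMap,
    alpha: float = DEFAULT_ALPHA,
    correction: str = "product",
    keep_all: bool = False,
) -> list[ModuleMatch]:
    """Reciprocal hypergeometric matching of two module partitions.

    The universe is the set of ortholog pairs (a, b) with ``a`` in a retained
    module of A and ``b`` in a retained module of B; module sizes are counted
    within that universe.  In many-to-many mode an A-gene overlaps a B-module
    when any of its orthologs is a member.  Returns reciprocal-significant
    matches unless ``keep_all`` is set.
    """
    genes_a_mod = {g for genes in part_a.modules.values() for g in genes}
    genes_b_mod = {g for genes in part_b.modules.values() for g in genes}
    universe_pairs = [
        (a, b)
        for a, b in omap.pairs
        if a in genes_a_mod and b in genes_b_mod
    ]
    universe_a = {a for a, _ in universe_pairs}
    universe_b = {b for _, b in universe_pairs}
    universe = len(universe_a)  # = len(universe_b) under a 1:1 map
    if universe == 0:
        logger.warning("empty matching universe; no module matches possible")
        return []
    m_a, m_b = part_a.n_modules, part_b.n_modules
    factor = _bonferroni_factor(m_a, m_b, correction)
    image_in_b = {a: omap.image(a) & universe_b for a in universe_a}
    preimage_in_a = {b: omap.preimage(b) & universe_a for b in universe_b}
    matches: list[ModuleMatch] = []
    for mid_a in sorted(part_a.modules):
        members_a = part_a.modules[mid_a] & universe_a
        if not members_a:
            continue
        for mid_b in sorted(part_b.modules):
            members_b = part_b.modules[mid_b] & universe_b
            if not members_b:
                continue
            # measure each direction entirely on one side of the map: the
            # other module enters as its orthology footprint on that side
            footprint_b_in_a = {
                a for a in universe_a if image_in_b[a] & members_b
            }
            footprint_a_in_b = {
                b for b in universe_b if preimage_in_a[b] & members_a
            }
            overlap_ab = len(members_a & footprint_b_in_a)
            overlap_ba = len(members_b & footprint_a_in_b)
            if overlap_ab == 0 and overlap_ba == 0 and not keep_all:
                continue
            p_ab = hypergeom_overlap_p(
                overlap_ab, len(members_a), len(footprint_b_in_a), universe
            )
            p_ba = hypergeom_overlap_p(
                overlap_ba, len(members_b), len(footprint_a_in_b), len(universe_b)
            )
            corr_ab = min(1.0, p_ab * factor)
            corr_ba = min(1.0, p_ba * factor)
            significant = corr_ab < alpha and corr_ba < alpha
            if significant or keep_all:
                matches.append(
                    ModuleMatch(
                        module_a=mid_a,
                        size_a=len(part_a.modules[mid_a]),
                        module_b=mid_b,
                        size_b=len(part_b.modules[mid_b]),
                        overlap=overlap_ab,
                        universe=universe,
                        p_a_to_b=p_ab,
                        p_b_to_a=p_ba,
                        corrected_a_to_b=corr_ab,
                        corrected_b_to_a=corr_ba,
                        reciprocal_significant=significant,
                    )
                )
    return matches


def match_against_genesets(
    part: ModulePartition,
    genesets: dict[str, set[str]],
    alpha: float = DEFAULT_ALPHA,
    universe: set[str] | None = None,
    keep_all: bool = False,
) -> list[dict]:
    """One-directional corrected hypergeometric matching of modules to gene
    sets (protein complexes, functional categories) of the same species."""
    module_genes = {g for genes in part.modules.values() for g in genes}
    if universe is None:
        universe = module_genes | {g for s in genesets.values() for g in s}
    n_tests = part.n_modules * len(genesets) or 1
    out: list[dict] = []
    for mid in sorted(part.modules):
        members = part.modules[mid] & universe
        if not members:
            continue
        for name in sorted(genesets):
            gset = genesets[name] & universe
            if not gset:
                continue
            overlap = len(members & gset)
            if overlap == 0 and not keep_all:
                continue
            p = hypergeom_overlap_p(overlap, len(members), len(gset), len(universe))
            corrected = min(1.0, p * n_tests)
            if corrected < alpha or keep_all:
                out.append(
                    {
                        "module": mid,
                        "geneset": name,
                        "module_size": len(members),
                        "geneset_size": len(gset),
                        "overlap": overlap,
                        "universe": len(universe),
                        "p": p,
                        "corrected_p": corrected,
                        "significant": corrected < alpha,
                    }
                )
    return out
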