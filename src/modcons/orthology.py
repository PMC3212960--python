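"""Gene correspondences between two species.

The primary mapping is one-to-one: a curated pair list takes precedence, and
reciprocal best BLASTP hits (RBH) fill in the rest.  A gene pair (a, b) is an
RBH when b is a's unique minimum-E-value hit in the other species and vice
versa; ties for the best hit disqualify the gene rather than being broken by
secondary scores.  Curated many-to-many groups are resolved to one-to-one
pairs by RBH restricted to the group's members.  A many-to-many mode is also
supported, under which an edge counts as conserved if *any* combination of
ortholog images is connected in the reference species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .io_formats import RawEdgeList

logger = logging.getLogger(__name__)


@dataclass
class OrthologyMap:
    """Gene correspondence between species A and species B."""

    species_a: str
    species_b: str
    pairs: set[tuple[str, str]] = field(default_factory=set)
    mode: str = "one_to_one"  # or "many_to_many"
    provenance: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("one_to_one", "many_to_many"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "one_to_one" and not self.is_injective():
            raise ValueError("one_to_one map has a gene in more than one pair")
        self._fwd: dict[str, set[str]] = {}
        self._bwd: dict[str, set[str]] = {}
        for a, b in self.pairs:
            self._fwd.setdefault(a, set()).add(b)
            self._bwd.setdefault(b, set()).add(a)

    def is_injective(self) -> bool:
        a_side = [a for a, _ in self.pairs]
        b_side = [b for _, b in self.pairs]
        return len(set(a_side)) == len(a_side) and len(set(b_side)) == len(b_side)

    def image(self, gene: str) -> set[str]:
        """Orthologs of an A-species gene in B (empty set if unmapped)."""
        return set(self._fwd.get(gene, set()))

    def preimage(self, gene: str) -> set[str]:
        return set(self._bwd.get(gene, set()))

    @property
    def mapped_a(self) -> set[str]:
        return set(self._fwd)

    @property
    def mapped_b(self) -> set[str]:
        return set(self._bwd)

    def reversed(self) -> "OrthologyMap":
        return OrthologyMap(
            species_a=self.species_b,
            species_b=self.species_a,
            pairs={(b, a) for a, b in self.pairs},
            mode=self.mode,
            provenance={(b, a): p for (a, b), p in self.provenance.items()},
        )


def _best_hits(hits: RawEdgeList, restrict_query=None, restrict_subject=None) -> dict[str, str]:
    """Unique minimum-E-value hit per query; queries with ties are dropped."""
    best: dict[str, tuple[float, str, bool]] = {}  # query -> (E, subject, tied)
    for q, s, evalue in hits.records:
        if evalue is None:
            raise ValueError("blast hits require E-values")
        if restrict_query is not None and q not in restrict_query:
            continue
        if restrict_subject is not None and s not in restrict_subject:
            continue
        cur = best.get(q)
        if cur is None or evalue < cur[0]:
            best[q] = (evalue, s, False)
        elif evalue == cur[0] and s != cur[1]:
            best[q] = (evalue, cur[1], True)
    return {q: s for q, (_, s, tied) in best.items() if not tied}


def reciprocal_best_hits(
    hits_ab: RawEdgeList,
    hits_ba: RawEdgeList,
    restrict_a=None,
    restrict_b=None,
    provenance: str = "rbh",
) -> OrthologyMap:
    """One-to-one orthologs from reciprocal best BLASTP hits."""
    if hits_ab.data_type != "blast_hit" or hits_ba.data_type != "blast_hit":
        raise ValueError("hit tables must be blast_hit edge lists")
    fwd = _best_hits(hits_ab, restrict_a, restrict_b)
    bwd = _best_hits(hits_ba, restrict_b, restrict_a)
    pairs = {(a, b) for a, b in fwd.items() if bwd.get(b) == a}
    return OrthologyMap(
        species_a=hits_ab.species,
        species_b=hits_ba.species,
        pairs=pairs,
        mode="one_to_one",
        provenance={p: provenance for p in pairs},
    )


def merge_curated(
    curated: RawEdgeList,
    rbh: OrthologyMap,
    hits_ab: RawEdgeList | None = None,
    hits_ba: RawEdgeList | None = None,
) -> OrthologyMap:
    """Combine a curated ortholog list with RBH pairs.

    Curated 1:1 pairs are kept verbatim.  Curated many-to-many groups
    (connected components of the curated pair graph with more than two
    genes) are resolved by RBH restricted to the group — using the hit
    tables when provided, otherwise by restricting the precomputed global
    RBH map.  Genes not covered by the curated list fall back to global RBH.
    """
    if curated.data_type != "curated_ortholog":
        raise ValueError("curated list must have data_type curated_ortholog")
    bip = nx.Graph()
    for a, b, _ in curated.records:
        bip.add_edge(("A", a), ("B", b))
    pairs: set[tuple[str, str]] = set()
    provenance: dict[tuple[str, str], str] = {}
    covered_a: set[str] = set()
    covered_b: set[str] = set()
    for comp in nx.connected_components(bip):
        a_genes = {g for side, g in comp if side == "A"}
        b_genes = {g for side, g in comp if side == "B"}
        covered_a |= a_genes
        covered_b |= b_genes
        if len(a_genes) == 1 and len(b_genes) == 1:
            pair = (next(iter(a_genes)), next(iter(b_genes)))
            pairs.add(pair)
            provenance[pair] = "curated"
            continue
        if hits_ab is not None and hits_ba is not None:
            sub = reciprocal_best_hits(
                hits_ab, hits_ba, restrict_a=a_genes, restrict_b=b_genes
            )
            resolved = sub.pairs
        else:
            resolved = {
                (a, b) for a, b in rbh.pairs if a in a_genes and b in b_genes
            }
        for pair in resolved:
            pairs.add(pair)
            provenance[pair] = "curated+rbh"
    for a, b in rbh.pairs:
        if a in covered_a or b in covered_b:
            continue
        taken_a = {x for x, _ in pairs}
        taken_b = {y for _, y in pairs}
        if a in taken_a or b in taken_b:
            continue
        pairs.add((a, b))
        provenance[(a, b)] = rbh.provenance.get((a, b), "rbh")
    return OrthologyMap(
        species_a=rbh.species_a or curated.species,
        species_b=rbh.species_b,
        pairs=pairs,
        mode="one_to_one",
        provenance=provenance,
    )


def restrict_to_map(net, omap: OrthologyMap):
    """Drop edges with an orthology-unmapped endpoint (comparable-edge set).

    Works on either network flavour; the mapped side is chosen by the
    network's species (falling back to the A side for unlabelled networks).
    """
    mapped = omap.mapped_b if net.species == omap.species_b else omap.mapped_a
    if hasattr(net, "data_type"):
        out = type(net)(species=net.species, data_type=net.data_type)
    else:
        out = type(net)(species=net.species)
    for row in net.edges():
        a, b = row[0], row[1]
        if a in mapped and b in mapped:
            out.add_edge(*row)
    return out


def identity_map(genes, species_a: str, species_b: str) -> OrthologyMap:
    """Identity orthology over a shared gene universe (self-comparison)."""
    pairs = {(g, g) for g in genes}
    return OrthologyMap(
        species_a=species_a,
        species_b=species_b,
        pairs=pairs,
        mode="one_to_one",
        provenance={p: "identity" for p in pairs},
    )
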