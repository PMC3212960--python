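"""Log-likelihood scoring of heterogeneous interaction evidence.

Each evidence type (co-expression, protein-protein interaction, genetic
interaction, sequence similarity) is converted into an undirected network
whose edges carry a log-likelihood score (LLS):

    LLS = ln[ (P(L|E) / P(!L|E)) / (P(L) / P(!L)) ]

where E is membership in an evidence-defined edge set (a correlation-rank bin
for expression, the whole edge set for binary evidence) and L is functional
linkage, operationalised as sharing a biological-process annotation.  Pairs
for which linkage cannot be decided (either gene unannotated) enter neither
the numerator nor the background.  Only positively scored edges are kept: an
LLS above zero means the evidence enriches for shared function relative to
chance.

For expression, gene pairs are ranked by Spearman correlation within each
experiment set, binned by rank, and every pair inherits its bin's LLS; a pair
observed in several experiment sets keeps the maximal score, which guards
against dependent experiment sets inflating scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
from scipy import stats

from .go_semantics import (
    DEFAULT_LARGE_TERM_FRACTION,
    AnnotationSet,
    filter_large_terms,
)
from .io_formats import ExpressionMatrix, RawEdgeList

logger = logging.getLogger(__name__)

#: Default number of gene pairs per correlation-rank bin.
DEFAULT_BIN_SIZE = 1000


class UnscorableError(ValueError):
    """Raised when an LLS cannot be computed (degenerate linkage counts)."""


@dataclass
class ScoredNetwork:
    """Undirected gene network of one species and evidence type.

    Edge weights are log-likelihood scores in natural-log units; every
    retained edge has a positive weight (the GO network, which carries raw
    similarities, is the one exception and is never integrated).
    """

    species: str
    data_type: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    def add_edge(self, a: str, b: str, weight: float) -> None:
        if a == b:
            raise ValueError(f"self-edge not allowed: {a!r}")
        self.graph.add_edge(a, b, weight=float(weight))

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def weight(self, a: str, b: str) -> float:
        return self.graph.edges[a, b]["weight"]

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, gene: str) -> int:
        return self.graph.degree(gene) if gene in self.graph else 0

    def edges(self):
        """Iterate over (gene_a, gene_b, weight) with a < b."""
        for a, b, d in self.graph.edges(data=True):
            x, y = sorted((a, b))
            yield x, y, d["weight"]

    def edge_set(self) -> set[tuple[str, str]]:
        return {(min(a, b), max(a, b)) for a, b in self.graph.edges()}


@dataclass
class LLSBin:
    lower: float
    upper: float
    n_pairs: int
    n_linked: int
    lls: float | None  # None when the bin is unscorable


@dataclass
class LLSBinTable:
    """Per-bin linkage counts and scores for one ranked evidence set."""

    bins: list[LLSBin]
    background: tuple[int, int]  # (total known pairs, total linked pairs)

    def __post_init__(self) -> None:
        for prev, cur in zip(self.bins, self.bins[1:]):
            if cur.lower < prev.upper - 1e-12:
                raise ValueError("bins must be ordered and non-overlapping")


class CoannotationReference:
    """Oracle deciding functional linkage of gene pairs from annotations.

    Two genes are *linked* when they share at least one annotation term after
    removal of uninformative large terms; *not linked* when both are annotated
    but share none; *unknown* when either gene is unannotated.  The background
    odds of linkage are taken over all annotated pairs of the species.
    """

    def __init__(
        self,
        ann: AnnotationSet,
        large_term_fraction: float = DEFAULT_LARGE_TERM_FRACTION,
        n_genes: int | None = None,
    ) -> None:
        filtered, _ = filter_large_terms(ann, large_term_fraction, n_genes)
        self.species = ann.species
        self._annotations = filtered.annotations
        self._genes = frozenset(filtered.annotations)
        n = len(self._genes)
        self.background_total = n * (n - 1) // 2
        by_term: dict[str, list[str]] = {}
        for g, terms in self._annotations.items():
            for t in terms:
                by_term.setdefault(t, []).append(g)
        linked: set[frozenset[str]] = set()
        for members in by_term.values():
            for a, b in combinations(members, 2):
                linked.add(frozenset((a, b)))
        self.background_linked = len(linked)

    def linkage(self, a: str, b: str) -> bool | None:
        """True = linked, False = not linked, None = unknown."""
        if a not in self._genes or b not in self._genes:
            return None
        return bool(self._annotations[a] & self._annotations[b])

    @property
    def background(self) -> tuple[int, int]:
        return self.background_total, self.background_linked

    def count_pairs(self, pairs) -> tuple[int, int]:
        """(known, linked) counts over an iterable of gene pairs."""
        known = linked = 0
        for a, b in pairs:
            status = self.linkage(a, b)
            if status is None:
                continue
            known += 1
            linked += status
        return known, linked


def compute_lls(
    n_pairs: int, n_linked: int, background_total: int, background_linked: int
) -> float:
    """Log-likelihood score for an edge set with known linkage counts.

    ``n_pairs`` counts only pairs with decidable linkage.  Degenerate bins
    (no linked or no unlinked pairs, or a degenerate background) are
    unscorable, not assigned an infinite score.
    """
    if not 0 <= n_linked <= n_pairs:
        raise ValueError("invalid linkage counts")
    if n_linked == 0 or n_linked == n_pairs:
        raise UnscorableError(
            f"bin with {n_linked}/{n_pairs} linked pairs has no finite LLS"
        )
    if not 0 < background_linked < background_total:
        raise UnscorableError("degenerate background linkage")
    odds_bin = n_linked / (n_pairs - n_linked)
    odds_bg = background_linked / (background_total - background_linked)
    return math.log(odds_bin / odds_bg)


def _bin_lls(
    known: int, linked: int, background: tuple[int, int]
) -> float | None:
    """Score one bin; None flags an unscorable bin.

    A fully linked bin has no finite odds ratio; it is scored with one pair
    reserved as unlinked, the most extreme finite value the counts support
    (a fully *unlinked* bin would score -inf and can never pass the
    positivity filter, so it is simply flagged).
    """
    if known == 0 or linked == 0:
        return None
    try:
        return compute_lls(known, linked, *background)
    except UnscorableError:
        if linked == known:
            return compute_lls(known + 1, linked, *background)
        return None


def spearman_pairs(
    expr: ExpressionMatrix, min_overlap: int = 3
) -> list[tuple[tuple[str, str], float]]:
    """Spearman correlation for all gene pairs of one expression matrix.

    Missing values are handled pairwise-complete; pairs with fewer than
    ``min_overlap`` shared arrays, or involving a constant profile, are
    omitted.
    """
    if min_overlap < 3:
        raise ValueError("min_overlap must be >= 3")
    values = expr.values
    genes = list(values.index)
    mat = values.to_numpy(dtype=float)
    if np.isnan(mat).any():
        corr = values.T.corr(method="spearman", min_periods=min_overlap)
        cmat = corr.to_numpy()
    else:
        if mat.shape[1] < min_overlap:
            return []
        ranks = np.apply_along_axis(stats.rankdata, 1, mat)
        sd = ranks.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cmat = np.corrcoef(ranks)
        cmat[sd == 0, :] = np.nan
        cmat[:, sd == 0] = np.nan
    out: list[tuple[tuple[str, str], float]] = []
    n_dropped = 0
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    for i, j in zip(iu, ju):
        scc = cmat[i, j]
        if np.isnan(scc):
            n_dropped += 1
            continue
        a, b = genes[i], genes[j]
        pair = (a, b) if a < b else (b, a)
        out.append((pair, float(scc)))
    if n_dropped:
        logger.warning(
            "%d gene pairs omitted (insufficient overlap or constant profile)",
            n_dropped,
        )
    return out


def bin_pairs_by_rank(
    scored_pairs: list[tuple[tuple[str, str], float]], bin_size: int
) -> list[list[tuple[tuple[str, str], float]]]:
    """Equal-count rank bins over pairs sorted by descending correlation.

    Ordering is fully deterministic: ties on the correlation are broken by
    the lexicographic gene pair and stay in the lower-rank (higher
    correlation) bin.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be positive")
    ordered = sorted(scored_pairs, key=lambda kv: (-kv[1], kv[0]))
    return [ordered[i : i + bin_size] for i in range(0, len(ordered), bin_size)]


def lls_bin_table(
    scored_pairs: list[tuple[tuple[str, str], float]],
    reference: CoannotationReference,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> LLSBinTable:
    bins = []
    for chunk in bin_pairs_by_rank(scored_pairs, bin_size):
        known, linked = reference.count_pairs(pair for pair, _ in chunk)
        lls = _bin_lls(known, linked, reference.background)
        bins.append(
            LLSBin(
                lower=min(s for _, s in chunk),
                upper=max(s for _, s in chunk),
                n_pairs=known,
                n_linked=linked,
                lls=lls,
            )
        )
    # bins were built in descending-SCC order; the table stores ascending
    bins.reverse()
    return LLSBinTable(bins=bins, background=reference.background)


def build_coexpression_network(
    experiments: list[ExpressionMatrix],
    reference: CoannotationReference,
    bin_size: int = DEFAULT_BIN_SIZE,
    min_overlap: int = 3,
) -> ScoredNetwork:
    """Co-expression network with per-pair LLS, maximal over experiment sets."""
    if not experiments:
        raise ValueError("at least one experiment set required")
    species = experiments[0].species
    if any(e.species != species for e in experiments):
        raise ValueError("experiments from mixed species")
    best: dict[tuple[str, str], float] = {}
    any_scorable = False
    for expr in experiments:
        scored = spearman_pairs(expr, min_overlap=min_overlap)
        for chunk in bin_pairs_by_rank(scored, bin_size):
            known, linked = reference.count_pairs(pair for pair, _ in chunk)
            lls = _bin_lls(known, linked, reference.background)
            if lls is None:
                continue
            any_scorable = True
            for pair, _ in chunk:
                if pair not in best or lls > best[pair]:
                    best[pair] = lls
    net = ScoredNetwork(species=species, data_type="coexpression")
    if not any_scorable:
        logger.warning("no scorable correlation bins; empty co-expression network")
        return net
    for (a, b), lls in best.items():
        if lls > 0:
            net.add_edge(a, b, lls)
    return net


def score_edge_set(
    pairs: list[tuple[str, str]],
    reference: CoannotationReference,
    species: str,
    data_type: str,
) -> ScoredNetwork:
    """Score an edge set as a single bin: one LLS shared by every edge.

    If the edge set is not enriched for co-annotation (LLS <= 0) the network
    is dropped (returned empty).  A fully linked edge set, for which the
    odds ratio has no finite value, is scored with one pair reserved as
    unlinked — the most extreme finite score the counts support.
    """
    net = ScoredNetwork(species=species, data_type=data_type)
    if not pairs:
        logger.warning("empty %s edge list for %s", data_type, species)
        return net
    known, linked = reference.count_pairs(pairs)
    if known == 0:
        raise UnscorableError(
            f"no annotated pairs among {data_type} edges of {species}"
        )
    try:
        lls = compute_lls(known, linked, *reference.background)
    except UnscorableError:
        if linked == known and known > 0:
            lls = compute_lls(known + 1, linked, *reference.background)
        else:
            raise
    if lls <= 0:
        logger.warning(
            "%s network of %s scored LLS=%.3f <= 0; dropped", data_type, species, lls
        )
        return net
    for a, b in pairs:
        net.add_edge(a, b, lls)
    return net


def build_binary_network(
    raw: RawEdgeList, reference: CoannotationReference
) -> ScoredNetwork:
    """Score a binary evidence network (PPI or genetic interactions)."""
    if raw.data_type not in {"ppi", "gi_positive", "gi_negative"}:
        raise ValueError(f"not a binary evidence type: {raw.data_type!r}")
    return score_edge_set(raw.pairs(), reference, raw.species, raw.data_type)


def build_sequence_network(
    self_hits: RawEdgeList,
    n_genes: int,
    reference: CoannotationReference,
    evalue_base: float = 1e-25,
) -> ScoredNetwork:
    """Paralogy network from self-BLASTP hits of a species against itself.

    Two distinct genes are connected when their best directed hit beats an
    E-value threshold of ``evalue_base`` divided by the number of genes in
    the species (a Bonferroni-style correction for database size); the edge
    set is then scored as binary evidence.
    """
    if self_hits.data_type != "blast_hit":
        raise ValueError("self_hits must be a blast_hit edge list")
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    threshold = evalue_base / n_genes
    best: dict[tuple[str, str], float] = {}
    for a, b, evalue in self_hits.records:
        if a == b or evalue is None:
            continue
        pair = (a, b) if a < b else (b, a)
        if pair not in best or evalue < best[pair]:
            best[pair] = evalue
    edges = sorted(pair for pair, e in best.items() if e < threshold)
    return score_edge_set(edges, reference, self_hits.species, "sequence")
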