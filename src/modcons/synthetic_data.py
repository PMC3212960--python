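"""Paired-species benchmark generator with known ground truth.

The generator emulates the statistical structure the pipeline is built to
measure: two species whose interactomes share planted orthologous modules,
with within-module edges conserved across species at a higher rate than
between-module edges.

Species A receives ``n_modules`` disjoint gene modules; edges are sampled
independently with a high density inside modules and a low density between
them.  A fraction of A's genes have a one-to-one ortholog in species B, and
each A-edge's image is carried to B with probability ``p_within`` or
``p_between`` according to its kind — conservation is planted at the *edge*
level because the conservation statistics are edge rates.  B additionally
gains independent noise edges at the between-module density, so B is never a
subgraph of A's image (mimicking incomplete and noisy coverage).  Every edge
is assigned to one or more evidence types (co-expression, PPI, positive GI,
sequence) by per-type coverage fractions.

The scenario also carries correlated expression matrices (module members
share a latent profile), a toy ontology with one term per module plus an
optional uninformative large term, cross- and self-species BLAST hit lists,
and a partly curated ortholog list, so every scoring stage of the pipeline
can run end-to-end on synthetic inputs alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from .clustering import ModulePartition
from .edge_scoring import (
    CoannotationReference,
    ScoredNetwork,
    build_sequence_network,
    score_edge_set,
)
from .go_semantics import AnnotationSet, OntologyDAG
from .integration import IntegratedNetwork, integrate
from .io_formats import (
    ExpressionMatrix,
    RawEdgeList,
    write_edge_list,
    write_expression,
    write_orthology,
)
from .orthology import OrthologyMap

logger = logging.getLogger(__name__)

ROOT_TERM = "GO:0000001"
LARGE_TERM = "GO:0999999"

_EVIDENCE_DEFAULTS = {
    "coexpression": 0.5,
    "ppi": 0.4,
    "gi_positive": 0.3,
    "sequence": 0.2,
}


@dataclass
class ScenarioConfig:
    """Study conditions for one paired-species scenario."""

    seed: int = 0
    n_genes: int = 2000
    n_modules: int = 125
    module_size_min: int = 12
    module_size_max: int = 20
    orthology_coverage: float = 0.9
    within_density: float = 0.9
    between_density: float = 0.0016
    core_fraction: float = 0.6
    peripheral_within_edges: int = 3
    peripheral_propensity: float = 1.0
    p_within: float = 0.5
    p_between: float = 0.1
    evidence_coverage: dict[str, float] = field(
        default_factory=lambda: dict(_EVIDENCE_DEFAULTS)
    )
    n_experiments: int = 1
    n_arrays: int = 30
    correlation_strength: float = 0.8
    noise_sd: float = 1.0
    curated_fraction: float = 0.3
    inject_large_term: bool = True
    large_term_gene_fraction: float = 0.06

    def validate(self) -> None:
        probs = [
            self.orthology_coverage,
            self.within_density,
            self.between_density,
            self.p_within,
            self.p_between,
            *self.evidence_coverage.values(),
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("densities and probabilities must lie in [0, 1]")
        if self.within_density <= self.between_density:
            raise ValueError("planted structure requires within > between density")
        if not 0.0 < self.core_fraction <= 1.0:
            raise ValueError("core_fraction must be in (0, 1]")
        if not 0.0 < self.peripheral_propensity <= 1.0:
            raise ValueError("peripheral_propensity must be in (0, 1]")
        if self.peripheral_within_edges < 1:
            raise ValueError("peripheral genes need at least one module edge")
        if not 0.0 < self.correlation_strength < 1.0:
            raise ValueError("correlation strength must be in (0, 1)")
        if self.module_size_min < 1 or self.module_size_max < self.module_size_min:
            raise ValueError("bad module size range")
        # modules tile the genome (every gene sits in exactly one module,
        # mirroring the exhaustive partition the clustering stage produces),
        # so the size range must admit an exact partition of the gene set
        if not (
            self.n_modules * self.module_size_min
            <= self.n_genes
            <= self.n_modules * self.module_size_max
        ):
            raise ValueError(
                "module sizes cannot tile the gene set: need "
                "n_modules*size_min <= n_genes <= n_modules*size_max"
            )


@dataclass
class GroundTruth:
    """Planted structure behind one scenario."""

    modules_a: dict[int, frozenset[str]]
    modules_b: dict[int, frozenset[str]]
    orthology_pairs: set[tuple[str, str]]
    #: A-edge -> {"kind": within|between, "conserved": bool, "evidence": [...]}
    edge_labels: dict[tuple[str, str], dict]
    #: B-edge -> {"origin": image|noise, "evidence": [...]}
    edges_b: dict[tuple[str, str], dict]

    def partition(self, species: str) -> ModulePartition:
        modules = self.modules_a if species == "A" else self.modules_b
        assigned = {g for genes in modules.values() for g in genes}
        if species == "A":
            universe = {g for e in self.edge_labels for g in e}
        else:
            universe = {g for e in self.edges_b for g in e}
        return ModulePartition(
            species=species,
            modules=dict(modules),
            unassigned=universe - assigned,
            parameters={"method": "planted"},
        )

    def to_dict(self) -> dict:
        return {
            "modules_a": {str(k): sorted(v) for k, v in self.modules_a.items()},
            "modules_b": {str(k): sorted(v) for k, v in self.modules_b.items()},
            "orthology_pairs": sorted(map(list, self.orthology_pairs)),
            "edge_labels": {
                f"{a}|{b}": lab for (a, b), lab in sorted(self.edge_labels.items())
            },
            "edges_b": {
                f"{a}|{b}": lab for (a, b), lab in sorted(self.edges_b.items())
            },
        }


@dataclass
class Scenario:
    """Generated inputs for both species plus the planted ground truth."""

    config: ScenarioConfig
    ground_truth: GroundTruth
    #: species -> evidence tag -> sorted list of gene pairs
    evidence_edges: dict[str, dict[str, list[tuple[str, str]]]]
    expression: dict[str, list[ExpressionMatrix]]
    dag: OntologyDAG
    annotations: dict[str, AnnotationSet]
    orthology: OrthologyMap
    curated: RawEdgeList
    cross_hits_ab: RawEdgeList
    cross_hits_ba: RawEdgeList
    self_hits: dict[str, RawEdgeList]

    def genes(self, species: str) -> list[str]:
        prefix = species.lower()
        return [f"{prefix}{i:04d}" for i in range(self.config.n_genes)]

    def raw_edge_list(self, species: str, tag: str) -> RawEdgeList:
        if tag not in ("ppi", "gi_positive", "gi_negative"):
            raise ValueError(f"no raw edge list for evidence tag {tag!r}")
        records = [(a, b, None) for a, b in self.evidence_edges[species].get(tag, [])]
        return RawEdgeList(species=species, data_type=tag, records=records)

    def reference(self, species: str) -> CoannotationReference:
        return CoannotationReference(
            self.annotations[species], n_genes=self.config.n_genes
        )

    def scored_networks(
        self, species: str, reference: CoannotationReference | None = None
    ) -> list[ScoredNetwork]:
        """LLS-scored evidence networks built from the planted edge lists."""
        ref = reference if reference is not None else self.reference(species)
        nets = []
        for tag in ("coexpression", "ppi", "gi_positive"):
            pairs = self.evidence_edges[species].get(tag, [])
            if pairs:
                nets.append(score_edge_set(pairs, ref, species, tag))
        if self.self_hits[species].records:
            nets.append(
                build_sequence_network(
                    self.self_hits[species], self.config.n_genes, ref
                )
            )
        return [n for n in nets if n.n_edges]

    def integrated(self, species: str) -> IntegratedNetwork:
        return integrate(self.scored_networks(species))

    # -- file emission ------------------------------------------------------

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        seed = self.config.seed
        for sp in ("A", "B"):
            for tag in ("ppi", "gi_positive"):
                write_edge_list(
                    self.raw_edge_list(sp, tag), out / f"{tag}_{sp}.tsv", seed=seed
                )
            coexp = RawEdgeList(
                species=sp,
                data_type="ppi",  # storage format only: two gene columns
                records=[
                    (a, b, None)
                    for a, b in self.evidence_edges[sp].get("coexpression", [])
                ],
            )
            write_edge_list(coexp, out / f"coexpression_{sp}.tsv", seed=seed)
            write_edge_list(self.self_hits[sp], out / f"self_blast_{sp}.tsv", seed=seed)
            for expr in self.expression[sp]:
                write_expression(
                    expr, out / f"expression_{sp}_{expr.experiment_id}.tsv", seed=seed
                )
            _write_gaf(self.annotations[sp], out / f"annotations_{sp}.gaf")
        _write_obo(self.dag, out / "ontology.obo")
        write_orthology(self.orthology, out / "orthology.tsv", seed=seed)
        write_edge_list(self.curated, out / "curated_orthologs.tsv", seed=seed)
        write_edge_list(self.cross_hits_ab, out / "blast_A_vs_B.tsv", seed=seed)
        write_edge_list(self.cross_hits_ba, out / "blast_B_vs_A.tsv", seed=seed)
        with (out / "ground_truth.json").open("w") as fh:
            json.dump(self.ground_truth.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")
        with (out / "scenario_config.json").open("w") as fh:
            json.dump(asdict(self.config), fh, indent=1, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# generation


def _module_term(m: int) -> str:
    return f"GO:{1000000 + m:07d}"


def generate_annotations(
    modules: dict[int, frozenset[str]],
    cfg: ScenarioConfig,
    genes: list[str],
    species: str,
    rng: np.random.Generator,
) -> tuple[OntologyDAG, AnnotationSet]:
    """Toy ontology: one term per module under a shared root.

    Module members are annotated to their module's term with experimental
    evidence.  Optionally a large term annotating more than the
    uninformative-term threshold of the genome is injected (computationally
    inferred evidence), exercising the large-term filter downstream.
    """
    g = nx.DiGraph()
    g.add_node(ROOT_TERM, name="root process")
    for m in sorted(modules):
        term = _module_term(m)
        g.add_node(term, name=f"module {m} process")
        g.add_edge(term, ROOT_TERM, relation="is_a")
    annotations: dict[str, set[str]] = {}
    evidence: dict[tuple[str, str], set[str]] = {}
    for m, members in sorted(modules.items()):
        for gene in sorted(members):
            annotations.setdefault(gene, set()).add(_module_term(m))
            evidence.setdefault((gene, _module_term(m)), set()).add("IDA")
    if cfg.inject_large_term:
        g.add_node(LARGE_TERM, name="very broad process")
        g.add_edge(LARGE_TERM, ROOT_TERM, relation="is_a")
        n_large = int(np.ceil(cfg.large_term_gene_fraction * len(genes)))
        chosen = rng.choice(len(genes), size=n_large, replace=False)
        for i in sorted(chosen):
            gene = genes[int(i)]
            annotations.setdefault(gene, set()).add(LARGE_TERM)
            evidence.setdefault((gene, LARGE_TERM), set()).add("IEA")
    dag = OntologyDAG(graph=g, namespace="biological_process")
    return dag, AnnotationSet(species=species, annotations=annotations, evidence=evidence)


def generate_expression(
    modules: dict[int, frozenset[str]],
    cfg: ScenarioConfig,
    genes: list[str],
    species: str,
    experiment_id: str,
    rng: np.random.Generator,
) -> ExpressionMatrix:
    """Expression matrix in which module members share a latent profile.

    A member's profile is sqrt(rho) * z_module + sqrt(1 - rho) * sd * noise,
    so the expected within-module correlation is rho/(rho + (1-rho) sd^2);
    non-members are pure noise.
    """
    import pandas as pd

    rho = cfg.correlation_strength
    n, k = len(genes), cfg.n_arrays
    latent = rng.standard_normal((len(modules), k))
    module_index = {m: i for i, m in enumerate(sorted(modules))}
    values = np.sqrt(1.0 - rho) * cfg.noise_sd * rng.standard_normal((n, k))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for m, members in sorted(modules.items()):
        z = latent[module_index[m]]
        for gene in members:
            values[gene_pos[gene]] += np.sqrt(rho) * z
    df = pd.DataFrame(
        np.round(values, 6),
        index=genes,
        columns=[f"array{j:03d}" for j in range(k)],
    )
    return ExpressionMatrix(species=species, values=df, experiment_id=experiment_id)


def _split_evidence(
    pairs: list[tuple[str, str]],
    coverage: dict[str, float],
    rng: np.random.Generator,
) -> tuple[dict[str, list[tuple[str, str]]], list[list[str]]]:
    """Distribute edges across evidence types, one type per edge.

    Coverage fractions act as relative shares of the edge set; each edge is
    observed by exactly one (randomly drawn) evidence type.
    """
    tags = sorted(coverage)
    weights = np.array([coverage[t] for t in tags], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("evidence coverage fractions must not all be zero")
    probs = weights / weights.sum()
    choice = rng.choice(len(tags), size=len(pairs), p=probs)
    by_tag: dict[str, list[tuple[str, str]]] = {t: [] for t in tags}
    labels: list[list[str]] = []
    for pair, c in zip(pairs, choice):
        tag = tags[int(c)]
        by_tag[tag].append(pair)
        labels.append([tag])
    return by_tag, labels


def _tiling_sizes(cfg: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Module sizes drawn from the configured range, summing to n_genes."""
    sizes = rng.integers(
        cfg.module_size_min, cfg.module_size_max + 1, cfg.n_modules
    ).astype(int)
    deficit = cfg.n_genes - int(sizes.sum())
    step = 1 if deficit > 0 else -1
    bound = cfg.module_size_max if deficit > 0 else cfg.module_size_min
    while deficit != 0:
        order = rng.permutation(cfg.n_modules)
        for i in order:
            if deficit == 0:
                break
            if sizes[i] * step < bound * step:
                sizes[i] += step
                deficit -= step
    return sizes


def generate_scenario(cfg: ScenarioConfig) -> Scenario:
    """Deterministically generate the full paired-species scenario."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    genes_a = [f"a{i:04d}" for i in range(n)]
    genes_b = [f"b{i:04d}" for i in range(n)]

    # planted modules tile A's gene set, mirrored onto B's gene indices
    sizes = _tiling_sizes(cfg, rng)
    perm = rng.permutation(n)
    mod_id = np.full(n, -1)
    pos = 0
    for m, s in enumerate(sizes):
        mod_id[perm[pos : pos + s]] = m
        pos += int(s)
    modules_a = {
        m: frozenset(genes_a[i] for i in np.flatnonzero(mod_id == m))
        for m in range(cfg.n_modules)
    }
    modules_b = {
        m: frozenset(genes_b[i] for i in np.flatnonzero(mod_id == m))
        for m in range(cfg.n_modules)
    }

    covered = rng.random(n) < cfg.orthology_coverage
    orthology_pairs = {
        (genes_a[i], genes_b[i]) for i in np.flatnonzero(covered)
    }
    omap = OrthologyMap(
        species_a="A",
        species_b="B",
        pairs=orthology_pairs,
        mode="one_to_one",
        provenance={p: "planted" for p in orthology_pairs},
    )

    # Modules have a core-periphery topology, as real functional modules do:
    # core members are densely interconnected, peripheral members hang off
    # the core by a few edges.  The resulting heavy-tailed degree profile
    # (many low-degree genes) is what lets MCL form modules on randomized
    # networks, as it does on real interactome data.
    is_core = np.zeros(n, dtype=bool)
    pos = 0
    for m, s in enumerate(sizes):
        members = perm[pos : pos + int(s)]
        n_core = max(2, int(np.ceil(cfg.core_fraction * int(s))))
        is_core[members[:n_core]] = True
        pos += int(s)

    within_set: set[tuple[int, int]] = set()
    pos = 0
    for m, s in enumerate(sizes):
        members = perm[pos : pos + int(s)]
        pos += int(s)
        core = [int(g) for g in members if is_core[g]]
        periph = [int(g) for g in members if not is_core[g]]
        for ci in range(len(core)):
            for cj in range(ci + 1, len(core)):
                if rng.random() < cfg.within_density:
                    a, b = core[ci], core[cj]
                    within_set.add((min(a, b), max(a, b)))
        for p in periph:
            k = min(cfg.peripheral_within_edges, len(core))
            for c in rng.choice(core, size=k, replace=False):
                a, b = p, int(c)
                within_set.add((min(a, b), max(a, b)))

    # between-module edges: per-pair probability proportional to the product
    # of the endpoints' propensities (core 1, periphery < 1), scaled so the
    # expected count matches the configured between-module density
    iu, ju = np.triu_indices(n, k=1)
    same_module = mod_id[iu] == mod_id[ju]
    propensity = np.where(is_core, 1.0, cfg.peripheral_propensity)
    pair_cc = propensity[iu] * propensity[ju]
    between_mask = ~same_module
    mean_cc = pair_cc[between_mask].mean()
    between_prob = np.minimum(1.0, cfg.between_density * pair_cc / mean_cc)
    b_draw = rng.random(iu.size)
    between_edge = between_mask & (b_draw < between_prob)

    ei_list, ej_list, within_flags = [], [], []
    for a, b in sorted(within_set):
        ei_list.append(a)
        ej_list.append(b)
        within_flags.append(True)
    for a, b in zip(iu[between_edge], ju[between_edge]):
        ei_list.append(int(a))
        ej_list.append(int(b))
        within_flags.append(False)
    ei = np.array(ei_list, dtype=int)
    ej = np.array(ej_list, dtype=int)
    e_within = np.array(within_flags, dtype=bool)
    cons_prob = np.where(e_within, cfg.p_within, cfg.p_between)
    conserved = rng.random(ei.size) < cons_prob

    # B noise edges at the between-module density, independent of A
    b_noise = rng.random(iu.size) < cfg.between_density

    a_pairs = [(genes_a[int(i)], genes_a[int(j)]) for i, j in zip(ei, ej)]
    image_pairs = {
        (genes_b[int(i)], genes_b[int(j)])
        for i, j, c in zip(ei, ej, conserved)
        if c
    }
    noise_pairs = {
        (genes_b[int(i)], genes_b[int(j)])
        for i, j in zip(iu[b_noise], ju[b_noise])
    }
    b_pair_origin = {p: "image" for p in sorted(image_pairs)}
    for p in sorted(noise_pairs - image_pairs):
        b_pair_origin[p] = "noise"
    b_pairs = sorted(b_pair_origin)

    ev_a, labels_a = _split_evidence(a_pairs, cfg.evidence_coverage, rng)
    ev_b, labels_b = _split_evidence(b_pairs, cfg.evidence_coverage, rng)

    edge_labels = {
        pair: {
            "kind": "within" if w else "between",
            "conserved": bool(c),
            "evidence": tags,
        }
        for pair, w, c, tags in zip(a_pairs, e_within, conserved, labels_a)
    }
    edges_b = {
        pair: {"origin": b_pair_origin[pair], "evidence": tags}
        for pair, tags in zip(b_pairs, labels_b)
    }

    ground_truth = GroundTruth(
        modules_a=modules_a,
        modules_b=modules_b,
        orthology_pairs=orthology_pairs,
        edge_labels=edge_labels,
        edges_b=edges_b,
    )

    # expression, annotations, hit lists
    expression = {}
    annotations = {}
    dag: OntologyDAG | None = None
    for sp, genes, modules in (("A", genes_a, modules_a), ("B", genes_b, modules_b)):
        expression[sp] = [
            generate_expression(modules, cfg, genes, sp, f"exp{e}", rng)
            for e in range(cfg.n_experiments)
        ]
        dag_sp, ann = generate_annotations(modules, cfg, genes, sp, rng)
        annotations[sp] = ann
        dag = dag_sp  # identical topology for both species; keep one

    self_hits = {}
    for sp, genes in (("A", genes_a), ("B", genes_b)):
        records = []
        seq_pairs = ev_a.get("sequence", []) if sp == "A" else ev_b.get("sequence", [])
        for a, b in seq_pairs:
            records.append((a, b, 1e-40))
            records.append((b, a, 1e-40))
        n_weak = min(200, n)
        wi = rng.integers(0, n, size=n_weak)
        wj = rng.integers(0, n, size=n_weak)
        for i, j in zip(wi, wj):
            if i != j:
                records.append((genes[int(i)], genes[int(j)], 1e-10))
        self_hits[sp] = RawEdgeList(species=sp, data_type="blast_hit", records=records)

    ab_records, ba_records = [], []
    for a, b in sorted(orthology_pairs):
        ab_records.append((a, b, 1e-60))
        ba_records.append((b, a, 1e-60))
    n_weak = min(300, n)
    for q, s, rec in (
        (genes_a, genes_b, ab_records),
        (genes_b, genes_a, ba_records),
    ):
        qi = rng.integers(0, n, size=n_weak)
        si = rng.integers(0, n, size=n_weak)
        for i, j in zip(qi, si):
            rec.append((q[int(i)], s[int(j)], 1e-5))
    cross_hits_ab = RawEdgeList(species="A", data_type="blast_hit", records=ab_records)
    cross_hits_ba = RawEdgeList(species="B", data_type="blast_hit", records=ba_records)

    sorted_pairs = sorted(orthology_pairs)
    n_curated = int(round(cfg.curated_fraction * len(sorted_pairs)))
    chosen = rng.choice(len(sorted_pairs), size=n_curated, replace=False)
    curated = RawEdgeList(
        species="A",
        data_type="curated_ortholog",
        records=[
            (sorted_pairs[int(i)][0], sorted_pairs[int(i)][1], None)
            for i in sorted(chosen)
        ],
    )

    evidence_edges = {
        "A": {t: sorted(v) for t, v in ev_a.items()},
        "B": {t: sorted(v) for t, v in ev_b.items()},
    }
    return Scenario(
        config=cfg,
        ground_truth=ground_truth,
        evidence_edges=evidence_edges,
        expression=expression,
        dag=dag,
        annotations=annotations,
        orthology=omap,
        curated=curated,
        cross_hits_ab=cross_hits_ab,
        cross_hits_ba=cross_hits_ba,
        self_hits=self_hits,
    )


# ---------------------------------------------------------------------------
# ontology/annotation writers (toy files; readers live in io_formats)


def _write_obo(dag: OntologyDAG, path: Path) -> None:
    with path.open("w") as fh:
        fh.write("format-version: 1.2\nontology: toy\n\n")
        for term in sorted(dag.terms):
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {dag.graph.nodes[term].get('name', term)}\n")
            fh.write(f"namespace: {dag.namespace}\n")
            for _, parent, data in dag.graph.out_edges(term, data=True):
                rel = data.get("relation", "is_a")
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")
            fh.write("\n")


def _write_gaf(ann: AnnotationSet, path: Path) -> None:
    with path.open("w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for gene in sorted(ann.annotations):
            for term in sorted(ann.annotations[gene]):
                codes = sorted(ann.evidence.get((gene, term), {"IDA"}))
                for code in codes:
                    fields = [
                        "toy",  # DB
                        gene,  # DB Object ID
                        gene,  # DB Object Symbol
                        "",  # Qualifier
                        term,  # GO ID
                        "toy:ref",  # DB:Reference
                        code,  # Evidence Code
                        "",  # With/From
                        "P",  # Aspect
                        "",  # DB Object Name
                        "",  # Synonym
                        "protein",  # DB Object Type
                        "taxon:0000",  # Taxon
                        "20200101",  # Date
                        "toy",  # Assigned By
                        "",  # Annotation Extension
                        "",  # Gene Product Form ID
                    ]
                    fh.write("\t".join(fields) + "\n")
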