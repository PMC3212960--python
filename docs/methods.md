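# Methods

This note documents the models, defaults and numerical choices behind
`modcons`, and what the synthetic benchmark does and does not establish.

## Evidence scoring

All evidence types are mapped onto a common currency, the log-likelihood
score (LLS) of functional linkage.  A pair of genes is *linked* when the two
genes share at least one biological-process annotation after removal of
large terms; it is *not linked* when both are annotated but share none;
pairs with an unannotated gene are *unknown* and enter neither the numerator
nor the background.  The background odds are taken over all annotated pairs
of the species.  Terms annotating more than `large_term_fraction` (default
0.05) of the species' genes are removed before any linkage or similarity
computation; the denominator is the species' total gene count, not the
annotated count, which matters for sparsely annotated genomes.

* **Co-expression.** Spearman correlations are computed for all gene pairs
  (pairwise-complete over missing values, `min_overlap` = 3 shared arrays;
  constant profiles are dropped).  Pairs are ranked by correlation within
  each experiment set and cut into equal-count bins (`bin_size` = 1000 pairs
  by default; ties are ordered by (−SCC, lexicographic pair) and stay in the
  higher-correlation bin).  Every pair inherits its bin's LLS; a pair seen
  in several experiment sets keeps the maximum, which protects against
  dependent experiment sets.  Only pairs with a final positive score become
  edges.
* **Binary evidence** (PPI, positive/negative genetic interaction). The
  whole edge set is one bin, so all edges share one LLS; a network whose
  LLS is ≤ 0 is dropped.
* **Sequence.** Two genes are paralog-linked when their best directed
  self-BLASTP hit has E < 1e-25 / n_genes (a database-size correction);
  the resulting edge set is scored as binary evidence.
* **Degenerate bins.** A bin with no linked or no unlinked known pairs has
  no finite odds ratio.  Fully *unlinked* bins are flagged unscorable (they
  could never pass the positivity filter).  Fully *linked* bins — routine in
  benchmarks where every gene is annotated — are scored with one pair
  reserved as unlinked, the most extreme finite value the counts support.

The GO network is different in kind: gene pairs are connected when their
Wang semantic similarity is ≥ 0.8.  Similarity of two terms is computed from
S-values — S_A(A) = 1, propagated to each ancestor as the maximum over paths
of the product of per-relation decay factors (is_a 0.8, part_of 0.6, the
canonical values) — combined as Σ(S₁+S₂ over shared ancestry) / (SV₁+SV₂);
gene-level similarity is the best-match average over the two annotation
sets.  The GO network carries raw similarities, not LLS, and is used for
comparison only.

## Integration and clustering

The integrated network sums each edge's LLS over co-expression, PPI,
positive GI and sequence evidence (independence assumption); negative GI —
which tends to connect parallel pathways rather than co-members — and the
GO network are never integrated.  A "no-seqs" variant omits sequence
evidence, and `exclude_paralog_edges` strips any edge whose endpoints hit
each other at E ≤ 1e-25 regardless of evidence type.

Markov Clustering is implemented directly on scipy sparse matrices.  The
column-stochastic transition matrix includes per-node self-loops equal to
the node's maximum incident edge weight (damping odd/even oscillation).
Each iteration applies expansion (matrix power, default 2), inflation
(entry-wise power, default 2.0, with column re-normalization) and pruning
(entries < 1e-5 dropped, always keeping each column's maximum), until the
entry-wise change falls below 1e-6 or 200 iterations.  Attractors are nodes
retaining diagonal flow above max(pruning, tolerance) — values below that
floor are numerical residue, not flow; attractors joined by flow form
systems, and each node joins the system receiving the largest share of its
column mass (ties to the smallest system id).  Nodes are sorted, so results
are independent of input order.  Modules below 3 genes are discarded; their
genes are reported as unassigned and later count toward baseline but
neither WMI nor BMI.

## Conservation statistics

All comparisons are directed (query → reference).  Comparable edges have
both endpoints orthology-mapped; under a many-to-many map an edge is
conserved if *any* combination of ortholog images is connected (or
co-clustered, for extended conservation).  Extended rates are cumulative —
direct OR co-module — so extended ≥ direct holds by construction, and the
report enforces it.  Rates with empty denominators are reported as
undefined (`None`), never zero.  Hub exclusion (default cutoff 300 when
enabled) removes every comparable edge incident to a high-degree node,
with degree measured on the query's integrated network.

Null models randomize the query species only.  Edge switching performs
10·|E| attempted double-edge swaps per evidence network (a standard mixing
heuristic), rejecting self- and multi-edges; each replacement edge inherits
the weight of the edge it replaces, so the degree sequence and the weight
multiset are preserved exactly.  Each replicate re-integrates the
randomized evidence networks, re-runs MCL, and recomputes the full report
against the real reference.  Empirical p-values use the add-one rule, so
p can never be zero — at 1000 replicates the strongest attainable claim is
p < 0.001.  Replicate sub-seeds are drawn up front from the master seed.

Module matching uses the upper-tail hypergeometric probability on the
universe of ortholog pairs whose genes sit in retained modules of both
species; each direction is measured entirely on one species' side of the
map, with the other module entering as its orthology footprint.  Raw
p-values are Bonferroni-multiplied by m_A·m_B (the number of pairwise tests;
a `sum` variant is available) and capped at 1; a pair of modules matches
when both corrected p-values fall below α = 0.05.

## The synthetic benchmark

`synthetic_data` generates the statistical structure the analysis is
designed to detect, with full ground truth.  Design choices that matter:

* **Modules tile the genome.**  Every gene belongs to exactly one planted
  module (sizes drawn from 12–20 and adjusted to sum to n_genes),
  mirroring MCL's exhaustive partition and making between-module edges
  classifiable rather than unclassified.
* **Core–periphery topology.**  Each module has a dense core
  (`core_fraction` = 0.6 of members, pairwise density `within_density` =
  0.9) and peripheral members attached by `peripheral_within_edges` = 3
  edges to the core.  Real functional modules are core–periphery rather
  than uniform blocks, and the resulting low-degree periphery is what lets
  MCL form modules on degree-preserving randomizations — on homogeneous
  planted blocks, edge-switched networks collapse to all-singleton
  attractors and the null statistics would be undefined.
* **Edge-level conservation.**  Each A-edge's image exists in B with
  probability `p_within` = 0.5 or `p_between` = 0.1 by kind, because the
  measured statistics are edge rates.  B additionally gains independent
  noise edges at the between-module density, so B is not a subgraph of A's
  image.  Orthology covers 90% of genes; uncovered genes have no
  counterpart and drop out of comparable denominators.
* **One evidence type per edge.**  Coverage fractions act as relative
  shares (co-expression 0.5, PPI 0.4, positive GI 0.3, sequence 0.2,
  normalized).  Letting one edge join several evidence types gives
  multi-evidence edges up to 4× integrated weight; such heavy edges act as
  inflation nuclei that split planted cores during clustering.
* **Annotations and expression.**  A toy ontology holds one term per
  module under a shared root (plus an optional large term annotating 6% of
  genes, exercising the 5% filter); module members are annotated to their
  term, making within-module pairs reference-linked.  Expression profiles
  are sqrt(ρ)·z_module + sqrt(1−ρ)·σ·ε with ρ = 0.8, σ = 1, so expected
  within-module correlation is ρ/(ρ+(1−ρ)σ²) = 0.8.
* **Scale.**  Defaults are n_genes = 2000, 125 modules,
  `between_density` = 0.0016 — about 7 300 within- and 2 700
  between-module edges, giving ≥ 2000 comparable edges in each class while
  keeping cross-module degree low enough (≈ 3 per gene) for clean planted
  recovery.  The full pipeline runs in seconds and a 100-replicate
  edge-switch null in under three minutes on one CPU; these sizes were
  chosen as the package's benchmark conditions.

What passing on this benchmark shows: the pipeline recovers planted
edge-conservation probabilities through clustering (not from ground-truth
labels), and the WMI−BMI contrast vanishes — on average slightly reverses —
under degree-preserving randomization.  What it does not show: behaviour
under real-data pathologies (probe-level microarray noise, study bias in
interaction coverage, heavy-tailed hub distributions beyond the mild
core–periphery contrast, ortholog misassignment), nor any of the published
per-species numbers, which require the original four-species datasets.

## Known limitations

* The conservation probability of a synthetic edge is independent of its
  evidence type; per-type conservation contrasts (strong in real data)
  are not emulated.
* The generator's BLAST hit lists are written directly (no sequences are
  simulated); E-values are placeholders on the correct side of the
  thresholds.
* `merge_curated` resolves curated many-to-many groups with RBH restricted
  to the group only when hit tables are supplied; otherwise it restricts
  the global RBH map, which can leave group members unmapped if their
  global best hit lies outside the group.
* MCL granularity is controlled by a single inflation default (2.0); no
  parameter sweep or resolution diagnostic is provided beyond
  `partition_overlap` for comparing alternative runs.
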