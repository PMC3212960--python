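# modcons — interaction-network conservation at the module level

Cross-species comparisons of high-throughput interaction data (co-expression,
protein–protein interactions, genetic interactions, sequence similarity)
consistently find that individual edges are poorly conserved even between
closely related organisms, while the underlying biological processes clearly
are.  `modcons` implements the analysis that reconciles this: interactions are
conserved not edge-by-edge but at the level of **functional modules** —
densely interacting gene sets found by clustering an integrated evidence
network.  Edges *within* a module are conserved at much higher rates than
edges *between* modules, and much of the residual loss is explained by
"extended" conservation, where the orthologs of an edge's endpoints still
share a module in the other species even if the specific edge was lost or
never measured.

The package is aimed at computational biologists who want to run this
analysis on their own paired-species edge lists, or study its statistical
behaviour on synthetic benchmarks with known ground truth.

## The statistics

Every evidence type is first converted into a weighted network by
log-likelihood scoring.  For an evidence-defined edge set *E* (a
correlation-rank bin for expression; the whole edge set for binary evidence),

```
LLS(E) = ln [ P(L|E)/P(¬L|E) ] − ln [ P(L)/P(¬L) ]
```

where *L* is functional linkage — sharing a biological-process annotation
after uninformative large terms (>5% of the genome) are removed.  Only
positively scored edges are kept; per-species networks are integrated by
summing LLS over evidence types, and the integrated network is partitioned
with Markov Clustering (MCL; expansion 2, inflation 2.0 by default), keeping
modules of ≥ 3 genes.

For a directed comparison of query species *A* against reference *B*, an
edge (g₁, g₂) of *A* is **comparable** when both genes have orthologs
(curated pairs plus reciprocal best BLASTP hits) in *B*, and

* **directly conserved** if the ortholog images are connected in *B*;
* **WMI / BMI** if its endpoints share / do not share a retained module of *A*;
* **extended-conserved** if it is directly conserved *or* its images share a
  retained module of *B*.

Rates are compared against two null models applied to the query species
only: degree-preserving edge switching and node-label permutation, each
followed by full re-clustering; empirical p-values use an add-one rule,
p = (1 + #{null ≥ obs}) / (n + 1).  Modules themselves are matched across
species by reciprocal Bonferroni-corrected hypergeometric overlap on the
orthology-mapped universe.

## Worked example

There is no bundled organism data; the `synthetic_data` module generates a
two-species benchmark with planted modules whose within-module edges are
carried across species with probability 0.5 and between-module edges with
probability 0.1 (the package defaults):

```python
from modcons.pipeline import run_comparison
from modcons.synthetic_data import ScenarioConfig, generate_scenario

scenario = generate_scenario(ScenarioConfig(seed=42))
result = run_comparison(scenario)
rep = result.report

print(f"comparable edges: {rep.n_comparable_edges} "
      f"(WMI {rep.n_wmi}, BMI {rep.n_bmi}, unclassified {rep.n_unclassified})")
for key in ("baseline_direct", "wmi_direct", "bmi_direct",
            "wmi_extended", "bmi_extended"):
    print(f"{key:>14}: {100 * rep.rate(key):.2f}%")
print(f"query modules: {result.part_a.n_modules}")
```

prints

```
comparable edges: 8504 (WMI 5732, BMI 2167, unclassified 605)
baseline_direct: 38.51%
    wmi_direct: 50.56%
    bmi_direct: 10.48%
  wmi_extended: 55.62%
  bmi_extended: 10.48%
query modules: 125
```

The pipeline estimate recovers the planted conservation probabilities (50.6%
vs 0.5 within, 10.5% vs 0.1 between) from the clustered modules alone: the
overall 38.5% baseline is revealed to be a mixture of two very different
edge populations.  Passing `null_method="edge_switch"` additionally runs the
degree-preserving null, where the WMI − BMI gap collapses to ≈ 0 (and on
average slightly below), confirming the gap is a property of the module
structure, not of the degree sequence.

The same stages are scriptable from a shell — `modcons simulate`, `score`,
`integrate`, `cluster`, `orthology`, `conserve`, `randomize`, `match`; see
`modcons --help`.

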