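# boolgrn

**From diet-perturbed transcriptomes to Boolean network dynamics.**

`boolgrn` is a tested, reusable implementation of a systems-biology analysis
chain that links a small two-group RNA-seq experiment (e.g. brain cortex of
mice on a normal diet, ND, vs a high-fat diet, HFD; 4 animals per group) to
the dynamics of an inferred Boolean gene-regulatory network:

1. **Normalization** — median-of-ratios size factors
   (s_j = median_g [ x_gj / (Π_j x_gj)^(1/m) ]), plus a mean–SD diagnostic.
2. **Differential expression** — an empirical-Bayes moderated t: per-gene
   pooled variances s² are shrunk toward a prior via
   s̃² = (d₀s₀² + d·s²)/(d₀ + d), with (d₀, s₀²) fit by method of moments on
   log s², and t = Δmean / (s̃·√(1/n₁+1/n₂)) on d₀+d degrees of freedom.
   Genes pass into up/down classes by p < α and |log₂FC| > 1.5.
3. **Directed network inference** — GENIE3-style: per target gene, a
   random-forest regression on all other candidate genes; the importance of
   a regulator is its total split variance reduction, normalized per target;
   edges are ranked and thresholded.
4. **Boolean rule learning** — expression is binarized per gene by an exact
   1-D two-cluster split; each gene's truth table is the best-fit extension
   (minimum sample disagreement) over its inferred parents.
5. **Synchronous dynamics** — exact attractor enumeration over the 2ⁿ state
   space with basin sizes, limit-cycle reports (which genes oscillate), and
   in-silico perturbations: clamping genes to 1 (over-expression) or 0
   (knockout), or restricting initial conditions.
6. **Topology metrics** — hubs, mean degree 2E/N, directed density
   E/(N(N−1)), mean closeness/betweenness, and the Shannon entropy of the
   degree distribution.

Because public accessions and unreported thresholds make published network
topologies irreproducible exactly, the package ships a first-class
**synthetic-data generator** that plants a known Boolean network, emits
negative-binomial counts from its steady states (ON genes high mean, OFF
genes low, per-sample log-normal library factors), and lets every stage be
scored against ground truth: edge-ranking AUPR, truth-table agreement, and
attractor-set overlap.

## Worked example

```python
from boolgrn import (GroundTruth, PipelineConfig, generate_network,
                     run_pipeline, score_recovery, simulate_expression)

net = generate_network(12, mean_in_degree=1.5, max_in_degree=3, seed=24)
# the "diet" perturbation: force one mostly-OFF gene on, one mostly-ON gene off
truth = GroundTruth(network=net, clamp_spec={"g05": 1, "g04": 0},
                    n_control=40, n_treated=40, mean_low=1.0, mean_high=100.0,
                    deterministic=True, library_sigma=0.3, seed=24)
counts, _ = simulate_expression(truth)

cfg = PipelineConfig(out_dir="demo_run", n_trees=100, seed=24)
report = run_pipeline(cfg, counts=counts)
print(report.summary["n_up"], report.summary["n_down"])
print(report.summary["n_attractors_baseline"],
      report.summary["n_attractors_perturbed"])
print(score_recovery(report, truth))
```

prints (numbers from this exact run):

```
3 4
11 3
{'edge_aupr': 0.254, 'rule_agreement': 0.573,
 'rule_agreement_reachable': 0.567, 'attractor_jaccard': 0.0,
 'n_shared_genes': 12}
```

Seven genes pass the differential-expression gates (3 up, 4 down); clamping
them to their diet-shifted values collapses the baseline landscape of 11
attractors to 3 — the same qualitative signature (many free-running steady
states, few under perturbation) this style of analysis looks for in real
data. The recovery scores quantify how much of the planted network the
pipeline got back: the edge ranking is ~2.3× better than a random one
(prevalence 0.11), and the fitted rules reproduce the planted update map on
57% of reachable-state evaluations. Single-condition equilibrium snapshots
carry limited causal information; for edge inference benchmarks use
`simulate_perturbation_panel`, which emits steady states under random gene
clamps (an in-silico knockout compendium) and supports AUPR ≳ 3× prevalence
at 60 samples.

Every stage is also exposed as a CLI subcommand
(`boolgrn simulate | normalize | de | infer | booleanize | attractors |
perturb | metrics | pipeline`), reading and writing plain-text formats
(count TSV + JSON sidecar, edge-list TSV, BoolNet-style rule files,
attractor JSON).

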