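# Methods

This note documents the models, estimators, conventions and design choices
behind `boolgrn`, stage by stage, and what the synthetic benchmarks do and do
not demonstrate about real data.

## The modelling frame

Gene activity is abstracted to binary states: a gene is ON (1) or OFF (0),
and a regulatory network is a set of per-gene Boolean update rules over
parent genes. Under synchronous update all genes apply their rules
simultaneously, so the dynamics is a deterministic map on the 2ⁿ state
space; every trajectory ends in a limit cycle (an *attractor*; a fixed point
is a cycle of length 1), and the states converging to a cycle form its
*basin*. Perturbations such as diet-induced over-expression or knockout are
modelled by *clamping*: holding a gene at 1 or 0 and removing it from the
free state space. The package also implements the weaker reading in which
perturbed genes are only *initialized* to the assigned value and then evolve
freely; clamping is the default because it matches knockout/over-expression
semantics and yields the stable single-attractor behaviour one expects from
a sustained dietary condition. Both are exposed (`perturb(..., mode=...)`).

## Synthetic data generator

The generator emulates the study design the analysis assumes: a small
two-group cohort of independent animals (default 4 ND vs 4 HFD), each
sample a single steady-state snapshot.

* **Network**: per-gene in-degrees are Poisson(mean_in_degree) truncated to
  [0, max_in_degree] (defaults 1.5 and 3); parents are sampled uniformly
  without self-loops; rules are drawn uniformly over *non-constant* Boolean
  functions of the parents (constant rules would freeze the dynamics and
  make every benchmark trivially easy or trivially impossible). In-degree-0
  genes get random constants.
* **Steady-state sampling**: per sample, a uniform random initial state is
  iterated to its attractor (treated samples with the clamp spec applied)
  and one cycle state is drawn uniformly. Samples are independent animals,
  not a trajectory — the data carry no temporal ordering.
* **Emission**: gene ON → NB(mean_high = 200, size = 10), OFF →
  NB(mean_low = 5, size = 10); each sample's means are multiplied by a
  log-normal library factor (σ = 0.3) so size-factor normalization is
  non-trivially exercised. A `deterministic` flag emits rounded means
  (noise-free limit) for recovery tests. The NB steady-state emission is a
  stand-in for real count noise, not a fitted model of any particular
  dataset.
* **Perturbation panels**: `simulate_perturbation_panel` draws, per sample,
  a random small set of genes (default 2) clamped to random values and
  samples the resulting steady state — an in-silico knockout/over-expression
  compendium. This is the study design directed network inference actually
  requires: at a single condition's equilibria, parent→child edges are not
  identifiable from pairwise dependence (we verified that even a
  mutual-information oracle on the true latent states ranks edges no better
  than ~1–1.5× prevalence), while interventional variation propagates each
  clamp through the network and lifts tree-ensemble recovery to ≥3×
  prevalence at 60 samples.

Everything is driven by one integer seed; identical seeds give bit-identical
outputs.

## Normalization

Median-of-ratios size factors: for sample j,
`s_j = median_g x_gj / r_g`, where the reference `r_g` is the geometric mean
of gene g over samples, restricted to genes with strictly positive counts in
every sample. Normalized values are `x_gj / s_j`; all log transforms are
`log2(normalized + 1)` with the pseudocount fixed at 1.

Size factors are only identified *relative to the reference*: re-estimating
the geometric means after rescaling one sample by c rescales every factor by
c^(1/m), so only factor ratios are equivariant. `size_factors` therefore
accepts an optional fixed per-gene reference (the geometric means of a
baseline cohort); against a fixed reference, factors are exactly equivariant
— scaling a sample by c scales its factor by c to machine precision and
leaves all other samples untouched.

The mean–SD diagnostic reports per-gene (mean, SD) of log-normalized values
with a running-median trend over rank-ordered means (window default 101,
minimum 3), for the usual variance-stabilization QC plot.

## Moderated t differential expression

On log2-normalized values, per gene: group means, pooled variance s² with
d = n₁+n₂−2 df. Across genes, s² is modelled as s₀²·F(d, d₀); the
hyperparameters are fit by method of moments on z = log s² using
`Var(z) = ψ′(d/2) + ψ′(d₀/2)` and
`E(z) = log s₀² + [ψ(d/2) − log(d/2)] − [ψ(d₀/2) − log(d₀/2)]`,
with the inverse trigamma solved by Newton iteration. The posterior variance
is s̃² = (d₀s₀² + d·s²)/(d₀+d) and t = Δmean/(s̃·√(1/n₁+1/n₂)) is referred to
t with d₀+d df. d₀ is clipped to [0.01, 10⁶] so the posterior df stay
finite; an infinite moment estimate (observed spread no larger than the
chi-square expectation) lands at the upper clip, i.e. effectively full
shrinkage. `d0_override` exposes the limits: 0 recovers the ordinary pooled
t exactly, ∞ gives every gene the common variance s₀². If fewer than two
genes have positive variance the prior cannot be identified and the
estimator falls back to full shrinkage toward the mean variance.

Multiple testing uses Benjamini–Hochberg (statsmodels). Classification
gates: a gene is *up* if p < α (default 0.05, raw p by default with a flag
for adjusted — both conventions are used in practice) and log₂FC > 1.5;
*down* with log₂FC < −1.5; otherwise *ns*. The ±1.5 cut is applied on the
log₂ scale; the base is a parameter.

Calibration: under a 2000-gene global null (4 vs 4, identical NB emission in
both groups) the raw p-value rate at 0.05 lands in [0.04, 0.06] (checked in
the acceptance suite).

## Network inference

GENIE3-style: for each target, a random-forest regression of the target's
standardized expression on all other candidate genes; regulator importance
is the impurity (variance) reduction summed over trees, normalized to sum
to 1 per target. Defaults are 1000 trees and √p features per split, the
original method's defaults. Two reproducibility choices:

* per-target sub-seeds are derived from (seed, target index) via
  `SeedSequence`, so results do not depend on the order targets are fitted;
* trees are grown **without bootstrap** (every tree sees all samples;
  randomness enters only through per-split feature subsampling) and the
  per-gene standardization moments are computed over sorted columns, so
  importances are bit-identical under any permutation of the samples.

Constant targets get a zero importance row and are flagged, not fatal.
Thresholding modes: `weight_min`, global `top_k_edges`, and the default
`top_k_per_target` with k = 2 — a per-target cap keeps fitted truth tables
small and the exact attractor search tractable. Isolated nodes are dropped
by default (mirroring how thresholding shrinks a candidate gene set to the
connected core).

## Binarization and rule fitting

Binarization is an exact 1-D two-cluster split per gene on log-normalized
values: all n−1 sorted split points are scanned with prefix sums and the
within-cluster sum of squares minimized (this *is* 1-D 2-means solved
exactly, with the first minimal split on ties); the higher-center cluster is
ON. Constant genes are flagged degenerate and set all-OFF.

Rule fitting is best-fit extension: the truth table minimizing the number of
samples where table(parent states) ≠ target state. The error decomposes
over input rows, so each observed row takes the majority target value; ties
and unobserved rows resolve to 0, which also realizes the global tie-break
(fewest ON outputs, then lexicographically smallest table) — fully
deterministic. The in-degree cap defaults to 3: with ~8 samples, larger
tables are unidentifiable, and small tables keep exact dynamics cheap.
Parents are ordered by descending inferred edge weight.

Rule files use the BoolNet text convention (`targets, factors` header, one
`gene, expression` line each, `!`/`&`/`|`/parentheses, constants 0/1).
Truth tables are written in disjunctive normal form; constant-output rules
serialize as bare constants (their parent list is dropped — the function
does not depend on it). Clamped genes are written as constants. Parse errors
name the offending line.

## Dynamics

States pack gene i at bit i in rule-file gene order. Exhaustive enumeration
builds a vectorized successor array over the free (unclamped) sub-space and
resolves every state by memoized pointer-chasing: exact attractors and exact
basin sizes, with basins partitioning 2^(free genes) by construction
(asserted in tests). The default capacity is 20 free genes (~10⁶ states),
configurable to 25 with a warning; beyond that, sampled mode walks random
initial states and reports estimated basins, flagged as such (and provably a
subset of the exhaustive attractor set). Cycle reports give each attractor's
length and the genes whose value differs between consecutive cycle states —
the "oscillating genes" of a limit cycle. Discrete two-state oscillations
are reported as plain 2-cycles; no continuous-bifurcation claims are made.

## Topology metrics

On the thresholded digraph: mean total degree 2E/N; directed density
E/(N(N−1)); closeness and betweenness on the *undirected view*, closeness
normalized within each node's connected component ((n_c−1)/Σd), betweenness
normalized by (N−1)(N−2)/2; degree entropy −Σ p_k log p_k over the empirical
total-degree distribution (natural log by default, base-2 flag); hubs are
all nodes at the maximum total degree, ties included. Published tables of
such metrics rarely state directedness, normalization or entropy base, so
every one of these conventions is switchable; the defaults are one
internally consistent reading. Path metrics are validated against a
Floyd–Warshall shortest-path oracle on all test graphs up to 12 nodes.

## Pipeline and recovery scoring

`run_pipeline` chains the stages, writing every intermediate as a documented
text artifact (size factors TSV, DE table TSV, importance and thresholded
edge lists, GraphML, binary states TSV, rule file, attractor JSONs, metrics
JSON, run report JSON with config hash and seed); stages communicate only
through these files, so each is independently re-runnable, and identical
configs produce byte-identical outputs. The treated-condition perturbation
is derived from the DEG classes (up → clamp 1, down → clamp 0) restricted to
network genes, with explicit overrides.

`score_recovery` reports, against the planted truth:

* **edge AUPR** — average precision of the importance ranking over all
  ordered gene pairs, labels from the planted edge list;
* **rule agreement** — mean fraction of agreeing truth-table rows per gene,
  over all assignments of the union of fitted and planted parent sets;
* **rule agreement (reachable)** — the same comparison evaluated only on
  the planted network's attractor states. This is the quantity steady-state
  snapshots can actually inform: cycle states violate same-time rule
  consistency (the rule maps state t to t+1) and rows never visited by the
  dynamics are unlearnable from equilibrium data, so the exhaustive
  agreement of a snapshot-fitted model plateaus well below 1 even with the
  true parent sets — a property of the design, not a defect of the fitter;
* **attractor Jaccard** — overlap of canonical attractor cycles projected
  onto the shared genes.

## Problem sizes in the test and acceptance runs

The shipped benchmarks use 8–12-gene networks for exact-dynamics oracle
comparisons (50 networks against a naive per-state walker), 15–20 genes with
60-sample perturbation panels for inference recovery, 2000 genes for the
null calibration, and 300-tree forests; these sizes give stable, seeded
results on a single CPU in seconds to a couple of minutes while exercising
every code path at full fidelity.

## Limitations

* Boolean abstraction: two activity levels, no graded or delayed regulation;
  synchronous update only (no asynchronous or probabilistic schemes).
* The generator's NB steady-state emission ignores gene-length effects,
  batch structure, and cell-composition heterogeneity; passing benchmarks
  show the chain is correct and recoverable under its own assumptions, not
  that any particular biological network is identifiable from 4-vs-4 data.
* Single-condition equilibrium snapshots do not identify directed edges;
  meaningful inference benchmarks (and real applications of tree-ensemble
  inference) need perturbation-diverse designs.
* Enrichment analysis against GO/KEGG/PPI databases is out of scope; a
  user-supplied gene-set file stands in for annotation-derived candidate
  sets.
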