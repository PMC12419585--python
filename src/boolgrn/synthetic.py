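"""Planted Boolean networks and synthetic two-group RNA-seq count matrices.

The generator emulates the design the downstream analysis assumes: a small
cohort of independent animals per diet group (default 4 control "ND" vs 4
treated "HFD"), each sample an independent draw from the steady-state
behaviour of a known regulatory network.  For every sample a random initial
state is iterated under synchronous update until it falls onto an attractor
(treated samples with the perturbed genes clamped), one attractor state is
picked uniformly, and counts are emitted per gene as negative binomial with a
high mean for ON genes and a low mean for OFF genes.  Per-sample log-normal
library-size factors make depth normalization non-trivial.

Because the planted network, the latent binary states and the clamp spec are
all returned, every downstream stage (normalization, differential expression,
network inference, rule fitting, attractor analysis) can be scored against
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CONTROL, TREATED, CountMatrix
from .network import BooleanNetwork


def generate_network(
    n_genes: int,
    mean_in_degree: float,
    max_in_degree: int,
    seed: int,
    allow_self_loops: bool = False,
) -> BooleanNetwork:
    """Draw a random Boolean network with roughly the requested in-degree.

    Per-gene in-degrees are Poisson(``mean_in_degree``) truncated to
    ``[0, max_in_degree]``; parents are sampled uniformly without replacement
    (self-loops excluded unless ``allow_self_loops``).  Each gene with at
    least one parent gets a Boolean function drawn uniformly over the
    *non-constant* functions of its parents; in-degree-0 genes get a random
    constant.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    if not (0 <= mean_in_degree <= max_in_degree):
        raise ValueError("need 0 <= mean_in_degree <= max_in_degree")
    if not (1 <= max_in_degree <= 4):
        raise ValueError("max_in_degree must be in 1..4")

    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes = [f"g{i + 1:0{width}d}" for i in range(n_genes)]
    parents: dict[str, list[str]] = {}
    tables: dict[str, tuple[int, ...]] = {}
    for i, g in enumerate(genes):
        pool = genes if allow_self_loops else genes[:i] + genes[i + 1:]
        k = min(int(rng.poisson(mean_in_degree)), max_in_degree, len(pool))
        ps = list(rng.choice(pool, size=k, replace=False)) if k else []
        parents[g] = [str(p) for p in ps]
        if k == 0:
            tables[g] = (int(rng.integers(0, 2)),)
        else:
            while True:
                bits = tuple(int(b) for b in rng.integers(0, 2, size=2 ** k))
                if any(bits) and not all(bits):
                    break
            tables[g] = bits
    return BooleanNetwork(genes=genes, parents=parents, truth_tables=tables)


@dataclass
class GroundTruth:
    """A planted network plus everything needed to emit counts from it.

    Parameters
    ----------
    network
        The planted Boolean network.
    clamp_spec
        The treated-group perturbation: genes held at 0/1 in HFD samples.
    mean_low, mean_high
        Negative-binomial mean counts for OFF / ON genes (``mean_high >
        mean_low > 0``).
    dispersion
        NB size parameter (larger = closer to Poisson).
    n_control, n_treated
        Samples per group (the emulated design is 4 vs 4).
    library_sigma
        SD of the per-sample log-normal library-size factor (0 disables it).
    deterministic
        Emit rounded means instead of NB draws (noise-free limit used by
        recovery tests).
    """

    network: BooleanNetwork
    clamp_spec: dict[str, int] = field(default_factory=dict)
    mean_low: float = 5.0
    mean_high: float = 200.0
    dispersion: float = 10.0
    n_control: int = 4
    n_treated: int = 4
    library_sigma: float = 0.3
    deterministic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.mean_high > self.mean_low > 0):
            raise ValueError("need mean_high > mean_low > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.n_control < 0 or self.n_treated < 0:
            raise ValueError("sample sizes must be non-negative")
        unknown = set(self.clamp_spec) - set(self.network.genes)
        if unknown:
            raise ValueError(f"clamp_spec genes not in network: {sorted(unknown)}")
        if any(v not in (0, 1) for v in self.clamp_spec.values()):
            raise ValueError("clamp values must be 0/1")


def _attractor_state(net: BooleanNetwork, rng: np.random.Generator) -> int:
    """Walk from a random initial state to an attractor, return one cycle
    state uniformly."""
    from .dynamics import successor

    n = net.n_genes
    s = int(rng.integers(0, 1 << min(n, 62)))
    if n > 62:  # build wide random states bitwise
        s = 0
        for i in range(n):
            s |= int(rng.integers(0, 2)) << i
    seen: dict[int, int] = {}
    path: list[int] = []
    limit = (1 << min(n, 25)) + 2  # finite deterministic map must cycle by then
    while s not in seen:
        if len(path) > limit:
            raise RuntimeError("attractor walk failed to close (internal error)")
        seen[s] = len(path)
        path.append(s)
        s = successor(net, s)
    cycle = path[seen[s]:]
    return cycle[int(rng.integers(0, len(cycle)))]


def simulate_expression(truth: GroundTruth) -> tuple[CountMatrix, pd.DataFrame]:
    """Emit a count matrix and the latent binary states behind it.

    Control samples run the unperturbed network; treated samples run it with
    ``clamp_spec`` clamped.  Same seed, same output, bit for bit.
    """
    rng = np.random.default_rng(truth.seed)
    net = truth.network
    genes = net.genes
    n = net.n_genes
    treated_net = net.with_clamped(dict(net.clamped) | truth.clamp_spec)

    sample_ids = [f"{CONTROL}_{i + 1}" for i in range(truth.n_control)] + [
        f"{TREATED}_{i + 1}" for i in range(truth.n_treated)
    ]
    labels = [CONTROL] * truth.n_control + [TREATED] * truth.n_treated

    states = np.zeros((n, len(sample_ids)), dtype=int)
    counts = np.zeros((n, len(sample_ids)), dtype=int)
    for j, lab in enumerate(labels):
        active_net = treated_net if lab == TREATED else net
        s = _attractor_state(active_net, rng)
        bits = np.array([(s >> i) & 1 for i in range(n)], dtype=int)
        states[:, j] = bits
        means = np.where(bits == 1, truth.mean_high, truth.mean_low).astype(float)
        if truth.library_sigma > 0:
            means = means * rng.lognormal(0.0, truth.library_sigma)
        if truth.deterministic:
            counts[:, j] = np.rint(means).astype(int)
        else:
            p = truth.dispersion / (truth.dispersion + means)
            counts[:, j] = rng.negative_binomial(truth.dispersion, p)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=sample_ids),
        condition=pd.Series(labels, index=sample_ids),
    )
    latent = pd.DataFrame(states, index=genes, columns=sample_ids)
    return cm, latent


def simulate_perturbation_panel(
    truth: GroundTruth,
    n_samples: int,
    n_clamped_per_sample: int = 2,
) -> tuple[CountMatrix, pd.DataFrame, list[dict[str, int]]]:
    """Steady states under random per-sample gene clamps — an in-silico
    knockout/over-expression compendium.

    Each sample clamps ``n_clamped_per_sample`` randomly chosen genes to
    random values, relaxes a random initial state to an attractor of the
    clamped network, and emits counts with the same NB/library-size model as
    :func:`simulate_expression`.  Clamping a regulator creates the
    interventional variation that directed network inference needs:
    single-condition equilibrium snapshots leave regulator->target edges
    unidentifiable, while a perturbation panel propagates each clamp through
    the network.  All samples are labelled as control; the per-sample clamp
    assignments are returned alongside the latent states.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not 0 <= n_clamped_per_sample <= truth.network.n_genes:
        raise ValueError("n_clamped_per_sample out of range")
    rng = np.random.default_rng(truth.seed)
    net = truth.network
    genes = net.genes
    n = net.n_genes
    sample_ids = [f"{CONTROL}_{j + 1}" for j in range(n_samples)]

    states = np.zeros((n, n_samples), dtype=int)
    counts = np.zeros((n, n_samples), dtype=int)
    clamps: list[dict[str, int]] = []
    for j in range(n_samples):
        picked = rng.choice(genes, size=n_clamped_per_sample, replace=False)
        clamp = {str(g): int(rng.integers(0, 2)) for g in picked}
        clamps.append(clamp)
        s = _attractor_state(net.with_clamped(dict(net.clamped) | clamp), rng)
        bits = np.array([(s >> i) & 1 for i in range(n)], dtype=int)
        states[:, j] = bits
        means = np.where(bits == 1, truth.mean_high, truth.mean_low).astype(float)
        if truth.library_sigma > 0:
            means = means * rng.lognormal(0.0, truth.library_sigma)
        if truth.deterministic:
            counts[:, j] = np.rint(means).astype(int)
        else:
            p = truth.dispersion / (truth.dispersion + means)
            counts[:, j] = rng.negative_binomial(truth.dispersion, p)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=sample_ids),
        condition=pd.Series([CONTROL] * n_samples, index=sample_ids),
    )
    latent = pd.DataFrame(states, index=genes, columns=sample_ids)
    return cm, latent, clamps
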