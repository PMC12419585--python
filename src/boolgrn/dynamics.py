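"""Exact synchronous Boolean-network dynamics.

States are packed as unsigned integers with gene ``i`` (network gene order)
at bit ``i``.  Under synchronous update every unclamped gene reads its truth
table simultaneously, so the dynamics is a deterministic map on the state
space and every trajectory ends in a limit cycle (a fixed point being a cycle
of length 1).  Attractors are enumerated exhaustively via a memoized
pointer-chase over a vectorized successor map, or estimated from random
initial states when the free space is too large.

Clamped genes are held at their assigned value and removed from the free
state space; an alternative "initial-state" perturbation only restricts the
initial conditions and lets the genes evolve freely afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import BooleanNetwork


@dataclass(frozen=True)
class Attractor:
    """One limit cycle: ordered states (canonical rotation) plus basin size."""

    states: tuple[int, ...]  # cycle states, rotated so the smallest is first
    basin_size: int  # number of (initial) states converging here

    @property
    def length(self) -> int:
        return len(self.states)


@dataclass
class AttractorSet:
    """All attractors found, with the search's bookkeeping.

    ``total_states`` is the number of initial states covered by the search
    (``2**n_free`` for exhaustive runs); for exhaustive searches the basin
    sizes partition it exactly, for sampled searches they are estimates and
    ``exact`` is False.
    """

    attractors: list[Attractor]
    genes: list[str]
    total_states: int
    exact: bool
    clamped: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.attractors)

    def state_to_bits(self, state: int) -> str:
        return "".join(str((state >> i) & 1) for i in range(len(self.genes)))

    def cycle_keys(self) -> set[tuple[int, ...]]:
        """Canonical cycle tuples, for set comparisons between searches."""
        return {a.states for a in self.attractors}

    def to_dict(self) -> dict:
        report = report_cycles(self)
        return {
            "genes": self.genes,
            "total_states": self.total_states,
            "exact_basins": self.exact,
            "clamped": self.clamped,
            "attractors": [
                {
                    "states": [self.state_to_bits(s) for s in a.states],
                    "cycle_length": a.length,
                    "basin_size": a.basin_size,
                    "oscillating_genes": report[i]["oscillating_genes"],
                }
                for i, a in enumerate(self.attractors)
            ],
        }


def _canonical_cycle(cycle: list[int]) -> tuple[int, ...]:
    k = cycle.index(min(cycle))
    return tuple(cycle[k:] + cycle[:k])


# ---------------------------------------------------------------------------
# Successor map
# ---------------------------------------------------------------------------


def successor(net: BooleanNetwork, state: int) -> int:
    """Synchronous successor of one packed state.

    Every unclamped gene is updated simultaneously from its truth table;
    clamped genes keep their clamped value regardless of the input state.
    """
    if not 0 <= state < (1 << net.n_genes):
        raise ValueError(f"state {state} out of range for {net.n_genes} genes")
    env = {g: (state >> i) & 1 for i, g in enumerate(net.genes)}
    nxt = 0
    for i, g in enumerate(net.genes):
        if g in net.clamped:
            bit = net.clamped[g]
        else:
            bit = net.evaluate_gene(g, env)
        nxt |= bit << i
    return nxt


def _free_successor_array(net: BooleanNetwork) -> tuple[np.ndarray, list[int], int]:
    """Vectorized successor map over the free (unclamped) sub-space.

    Returns ``(succ, free_idx, clamp_bits)`` where ``succ[f]`` is the free
    index of the successor of free index ``f``, ``free_idx`` lists the bit
    positions of unclamped genes, and ``clamp_bits`` carries the clamped
    genes' fixed values.
    """
    gene_pos = {g: i for i, g in enumerate(net.genes)}
    free_idx = [i for i, g in enumerate(net.genes) if g not in net.clamped]
    clamp_bits = 0
    for g, v in net.clamped.items():
        clamp_bits |= v << gene_pos[g]

    m = len(free_idx)
    f = np.arange(1 << m, dtype=np.int64)
    full = np.full(1 << m, clamp_bits, dtype=np.int64)
    for j, pos in enumerate(free_idx):
        full |= ((f >> j) & 1) << pos

    nxt_full = np.full(1 << m, clamp_bits, dtype=np.int64)
    for g in net.genes:
        if g in net.clamped:
            continue
        pos = gene_pos[g]
        row = np.zeros(1 << m, dtype=np.int64)
        for p in net.parents[g]:
            row = (row << 1) | ((full >> gene_pos[p]) & 1)
        table = np.asarray(net.truth_tables[g], dtype=np.int64)
        nxt_full |= table[row] << pos

    succ = np.zeros(1 << m, dtype=np.int64)
    for j, pos in enumerate(free_idx):
        succ |= ((nxt_full >> pos) & 1) << j
    return succ, free_idx, clamp_bits


def _expand(free_state: int, free_idx: list[int], clamp_bits: int) -> int:
    full = clamp_bits
    for j, pos in enumerate(free_idx):
        full |= ((free_state >> j) & 1) << pos
    return full


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------


def enumerate_attractors(
    net: BooleanNetwork,
    mode: str = "exhaustive",
    max_exhaustive_genes: int = 20,
    n_samples: int = 1000,
    seed: int = 0,
) -> AttractorSet:
    """Find the attractors of the synchronous dynamics.

    Parameters
    ----------
    mode
        ``"exhaustive"`` resolves every state of the free space via memoized
        pointer-chasing and returns exact basin sizes.  ``"sampled"`` walks
        ``n_samples`` random initial states; basin sizes are then estimates.
    max_exhaustive_genes
        Capacity guard for exhaustive mode (configurable up to 25; above 20
        a warning is issued).
    """
    if mode not in ("exhaustive", "sampled"):
        raise ValueError(f"unknown mode {mode!r}")
    n_free = net.n_genes - len(net.clamped)
    if mode == "exhaustive":
        cap = min(int(max_exhaustive_genes), 25)
        if n_free > cap:
            raise ValueError(
                f"exhaustive enumeration over {n_free} free genes exceeds the "
                f"cap of {cap}; use mode='sampled'"
            )
        if n_free > 20:
            warnings.warn(
                f"exhaustive enumeration over {n_free} free genes "
                f"({1 << n_free} states) may be slow", stacklevel=2
            )
        return _enumerate_exhaustive(net)
    return _enumerate_sampled(net, n_samples=n_samples, seed=seed)


def _enumerate_exhaustive(net: BooleanNetwork) -> AttractorSet:
    succ, free_idx, clamp_bits = _free_successor_array(net)
    n_states = succ.shape[0]
    comp = np.full(n_states, -1, dtype=np.int64)
    cycles: list[list[int]] = []

    for s0 in range(n_states):
        if comp[s0] >= 0:
            continue
        path: list[int] = []
        on_path: dict[int, int] = {}
        s = s0
        while comp[s] < 0 and s not in on_path:
            on_path[s] = len(path)
            path.append(s)
            s = int(succ[s])
        if comp[s] >= 0:
            aid = int(comp[s])
        else:
            aid = len(cycles)
            cycles.append(path[on_path[s]:])
        comp[path] = aid

    basins = np.bincount(comp, minlength=len(cycles))
    attractors = [
        Attractor(
            states=_canonical_cycle([_expand(s, free_idx, clamp_bits) for s in cyc]),
            basin_size=int(basins[i]),
        )
        for i, cyc in enumerate(cycles)
    ]
    attractors.sort(key=lambda a: a.states)
    return AttractorSet(
        attractors=attractors,
        genes=list(net.genes),
        total_states=n_states,
        exact=True,
        clamped=dict(net.clamped),
    )


def _enumerate_sampled(net: BooleanNetwork, n_samples: int, seed: int) -> AttractorSet:
    succ, free_idx, clamp_bits = _free_successor_array(net)
    n_states = succ.shape[0]
    rng = np.random.default_rng(seed)
    comp: dict[int, int] = {}
    cycles: list[list[int]] = []
    hits: dict[int, int] = {}

    starts = rng.integers(0, n_states, size=n_samples)
    for s0 in starts:
        s0 = int(s0)
        path: list[int] = []
        on_path: dict[int, int] = {}
        s = s0
        while s not in comp and s not in on_path:
            on_path[s] = len(path)
            path.append(s)
            s = int(succ[s])
        if s in comp:
            aid = comp[s]
        else:
            aid = len(cycles)
            cycles.append(path[on_path[s]:])
        for t in path:
            comp[t] = aid
        hits[aid] = hits.get(aid, 0) + 1

    attractors = [
        Attractor(
            states=_canonical_cycle([_expand(s, free_idx, clamp_bits) for s in cyc]),
            basin_size=hits[i],
        )
        for i, cyc in enumerate(cycles)
    ]
    attractors.sort(key=lambda a: a.states)
    return AttractorSet(
        attractors=attractors,
        genes=list(net.genes),
        total_states=n_samples,
        exact=False,
        clamped=dict(net.clamped),
    )


# ---------------------------------------------------------------------------
# Perturbation
# ---------------------------------------------------------------------------


def perturb(
    net: BooleanNetwork,
    up_genes: set[str] | list[str] = (),
    down_genes: set[str] | list[str] = (),
    mode: str = "clamp",
    max_exhaustive_genes: int = 20,
) -> AttractorSet:
    """Attractors of the network under an over-expression/knockout perturbation.

    ``up_genes`` are forced towards 1, ``down_genes`` towards 0.  In ``clamp``
    mode the genes are held fixed for the whole simulation (removed from the
    free space); in ``initial_state`` mode they are only initialized to the
    assigned value and free to evolve, so enumeration runs over exactly the
    initial states consistent with the assignment.
    """
    up, down = set(up_genes), set(down_genes)
    overlap = up & down
    if overlap:
        raise ValueError(f"genes in both up and down sets: {sorted(overlap)}")
    missing = (up | down) - set(net.genes)
    if missing:
        raise ValueError(f"unknown genes: {sorted(missing)}")
    assignment = {g: 1 for g in up} | {g: 0 for g in down}

    if mode == "clamp":
        clamped = dict(net.clamped) | assignment
        return enumerate_attractors(
            net.with_clamped(clamped),
            mode="exhaustive",
            max_exhaustive_genes=max_exhaustive_genes,
        )
    if mode == "initial_state":
        return _enumerate_restricted_initial(net, assignment, max_exhaustive_genes)
    raise ValueError(f"unknown mode {mode!r}")


def _enumerate_restricted_initial(
    net: BooleanNetwork, assignment: dict[str, int], max_exhaustive_genes: int
) -> AttractorSet:
    succ, free_idx, clamp_bits = _free_successor_array(net)
    pos_to_j = {pos: j for j, pos in enumerate(free_idx)}
    gene_pos = {g: i for i, g in enumerate(net.genes)}

    fixed_bits = 0
    fixed_mask = 0
    roam_js = []
    for j, pos in enumerate(free_idx):
        g = net.genes[pos]
        if g in assignment:
            fixed_bits |= assignment[g] << j
            fixed_mask |= 1 << j
        else:
            roam_js.append(j)
    for g, v in assignment.items():
        if g in net.clamped and net.clamped[g] != v:
            raise ValueError(f"gene {g!r} clamped to {net.clamped[g]}, assigned {v}")

    n_roam = len(roam_js)
    if n_roam > min(int(max_exhaustive_genes), 25):
        raise ValueError(
            f"{n_roam} unassigned genes exceed the exhaustive cap; "
            "use clamp mode or a larger cap"
        )

    comp: dict[int, int] = {}
    cycles: list[list[int]] = []
    basin: dict[int, int] = {}
    for r in range(1 << n_roam):
        s0 = fixed_bits
        for jj, j in enumerate(roam_js):
            s0 |= ((r >> jj) & 1) << j
        path: list[int] = []
        on_path: dict[int, int] = {}
        s = s0
        while s not in comp and s not in on_path:
            on_path[s] = len(path)
            path.append(s)
            s = int(succ[s])
        aid = comp[s] if s in comp else len(cycles)
        if s not in comp:
            cycles.append(path[on_path[s]:])
        for t in path:
            comp[t] = aid
        basin[aid] = basin.get(aid, 0) + 1

    attractors = [
        Attractor(
            states=_canonical_cycle([_expand(s, free_idx, clamp_bits) for s in cyc]),
            basin_size=basin[i],
        )
        for i, cyc in enumerate(cycles)
    ]
    attractors.sort(key=lambda a: a.states)
    return AttractorSet(
        attractors=attractors,
        genes=list(net.genes),
        total_states=1 << n_roam,
        exact=True,
        clamped=dict(net.clamped),
    )


# ---------------------------------------------------------------------------
# Cycle reporting
# ---------------------------------------------------------------------------


def report_cycles(attractors: AttractorSet) -> list[dict]:
    """Per-attractor cycle length and the genes that oscillate along it.

    A gene oscillates if its value differs between any pair of consecutive
    cycle states (the cycle wraps around); fixed points report an empty set.
    """
    out = []
    for a in attractors.attractors:
        diff = 0
        for i, s in enumerate(a.states):
            diff |= s ^ a.states[(i + 1) % len(a.states)]
        genes = [g for i, g in enumerate(attractors.genes) if (diff >> i) & 1]
        out.append({"cycle_length": a.length, "oscillating_genes": genes})
    return out
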