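"""Independent reference implementations used as test oracles.

Everything here is deliberately naive — direct formula evaluation, per-state
trajectory walks, exhaustive enumeration — and shares no code with the
package's optimized paths.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np


# ---------------------------------------------------------------------------
# Boolean dynamics: naive per-state trajectory walker
# ---------------------------------------------------------------------------


def naive_successor_table(net) -> dict[int, int]:
    """Successor of every packed state, by direct rule evaluation."""
    n = net.n_genes
    table = {}
    for s in range(1 << n):
        bits = {g: (s >> i) & 1 for i, g in enumerate(net.genes)}
        nxt = 0
        for i, g in enumerate(net.genes):
            if g in net.clamped:
                b = net.clamped[g]
            else:
                ps = net.parents[g]
                row = 0
                for p in ps:
                    row = row * 2 + bits[p]
                b = net.truth_tables[g][row]
            nxt |= b << i
        table[s] = nxt
    return table


def naive_attractors(net) -> dict[tuple[int, ...], int]:
    """Map canonical cycle -> exact basin size, walking every free state.

    Clamped genes are fixed at their value; only states consistent with the
    clamps are walked (the free state space).
    """
    succ = naive_successor_table(net)
    clamp_mask = 0
    clamp_bits = 0
    for g, v in net.clamped.items():
        i = net.genes.index(g)
        clamp_mask |= 1 << i
        clamp_bits |= v << i

    basins: dict[tuple[int, ...], int] = {}
    for s0 in range(1 << net.n_genes):
        if (s0 & clamp_mask) != clamp_bits:
            continue
        seen = {}
        path = []
        s = s0
        while s not in seen:
            seen[s] = len(path)
            path.append(s)
            s = succ[s]
        cycle = path[seen[s]:]
        k = cycle.index(min(cycle))
        key = tuple(cycle[k:] + cycle[:k])
        basins[key] = basins.get(key, 0) + 1
    return basins


# ---------------------------------------------------------------------------
# Normalization: brute-force median of ratios
# ---------------------------------------------------------------------------


def brute_force_size_factors(counts: np.ndarray) -> np.ndarray:
    """counts: genes x samples.  Literal median-of-ratios, gene by gene."""
    n_genes, n_samples = counts.shape
    ref = []
    for g in range(n_genes):
        row = counts[g]
        if all(c > 0 for c in row):
            gm = math.exp(sum(math.log(c) for c in row) / n_samples)
            ref.append((g, gm))
    factors = []
    for j in range(n_samples):
        ratios = sorted(counts[g, j] / gm for g, gm in ref)
        m = len(ratios)
        med = ratios[m // 2] if m % 2 else (ratios[m // 2 - 1] + ratios[m // 2]) / 2
        factors.append(med)
    return np.array(factors)


# ---------------------------------------------------------------------------
# Moderated t: moment equations solved independently
# ---------------------------------------------------------------------------


def brute_force_moderated_t(xc: np.ndarray, xt: np.ndarray):
    """Moderated t from scratch: pooled variances, scaled-F moments on
    log s^2 (prior df via scalar root finding), posterior shrinkage.

    xc, xt: samples x genes for control / treated.
    Returns (d0, s0_sq, t_values).
    """
    from scipy.optimize import brentq
    from scipy.special import digamma, polygamma

    n1, n2 = xc.shape[0], xt.shape[0]
    d = n1 + n2 - 2
    s2 = (
        ((xc - xc.mean(axis=0)) ** 2).sum(axis=0)
        + ((xt - xt.mean(axis=0)) ** 2).sum(axis=0)
    ) / d
    z = np.log(s2[s2 > 0])
    evar = z.var(ddof=1) - polygamma(1, d / 2)
    if evar > 0:
        half_d0 = brentq(lambda x: polygamma(1, x) - evar, 1e-8, 1e10)
        d0 = 2 * half_d0
    else:
        d0 = 1e6
    d0 = min(max(d0, 0.01), 1e6)
    s0 = math.exp(
        z.mean()
        - digamma(d / 2)
        + math.log(d / 2)
        + digamma(d0 / 2)
        - math.log(d0 / 2)
    )
    post = (d0 * s0 + d * s2) / (d0 + d)
    t = (xt.mean(axis=0) - xc.mean(axis=0)) / np.sqrt(post * (1 / n1 + 1 / n2))
    return d0, s0, t


# ---------------------------------------------------------------------------
# Binarization: exhaustive 1-D two-partition
# ---------------------------------------------------------------------------


def brute_force_two_partition(values) -> np.ndarray:
    """Exhaustive scan of all sorted split points minimizing within-cluster
    SS; returns 0/1 labels (higher-mean cluster = 1).  Constant input -> 0s."""
    values = list(values)
    if min(values) == max(values):
        return np.zeros(len(values), dtype=int)
    order = sorted(range(len(values)), key=lambda i: values[i])
    best_ss, best_k = None, None
    for k in range(1, len(values)):
        left = [values[order[i]] for i in range(k)]
        right = [values[order[i]] for i in range(k, len(values))]
        ml = sum(left) / len(left)
        mr = sum(right) / len(right)
        ss = sum((v - ml) ** 2 for v in left) + sum((v - mr) ** 2 for v in right)
        if best_ss is None or ss < best_ss:
            best_ss, best_k = ss, k
    labels = np.zeros(len(values), dtype=int)
    for i in range(best_k, len(values)):
        labels[order[i]] = 1
    return labels


# ---------------------------------------------------------------------------
# Rule fitting: exhaustive function-space scoring
# ---------------------------------------------------------------------------


def brute_force_best_rule(parent_rows, target_bits, k: int):
    """Score all 2^(2^k) truth tables, return the set of minimizers.

    parent_rows: per-sample row index (first parent most significant);
    target_bits: per-sample 0/1.
    """
    best_err, best = None, []
    for table in product((0, 1), repeat=2 ** k):
        err = sum(
            1 for r, y in zip(parent_rows, target_bits) if table[r] != y
        )
        if best_err is None or err < best_err:
            best_err, best = err, [table]
        elif err == best_err:
            best.append(table)
    return best_err, best


# ---------------------------------------------------------------------------
# Graph centralities: Floyd-Warshall / exhaustive path counting
# ---------------------------------------------------------------------------


def floyd_warshall_centralities(nodes, und_edges):
    """(closeness, betweenness) dicts from scratch on an undirected graph.

    Closeness is normalized within each node's reachable set; betweenness is
    normalized by (N-1)(N-2)/2 and counts shortest paths via all-pairs path
    counting on the Floyd-Warshall distance matrix.
    """
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    INF = float("inf")
    dist = [[0 if i == j else INF for j in range(n)] for i in range(n)]
    for u, v in und_edges:
        dist[idx[u]][idx[v]] = 1
        dist[idx[v]][idx[u]] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i][k] + dist[k][j] < dist[i][j]:
                    dist[i][j] = dist[i][k] + dist[k][j]

    # number of shortest s-t paths, by DP over increasing distance
    npaths = [[0] * n for _ in range(n)]
    for s in range(n):
        npaths[s][s] = 1
        order = sorted(
            (j for j in range(n) if dist[s][j] < INF), key=lambda j: dist[s][j]
        )
        for j in order:
            if j == s:
                continue
            total = 0
            for m in range(n):
                if (
                    dist[m][j] == 1
                    and dist[s][m] + 1 == dist[s][j]
                ):
                    total += npaths[s][m]
            npaths[s][j] = total

    closeness = {}
    for v in nodes:
        i = idx[v]
        reach = [j for j in range(n) if j != i and dist[i][j] < INF]
        if not reach:
            closeness[v] = 0.0
        else:
            closeness[v] = len(reach) / sum(dist[i][j] for j in reach)

    betweenness = {}
    norm = (n - 1) * (n - 2) / 2 if n > 2 else 1
    for v in nodes:
        i = idx[v]
        total = 0.0
        for s in range(n):
            for t in range(s + 1, n):
                if s == i or t == i or dist[s][t] == INF:
                    continue
                if dist[s][i] + dist[i][t] == dist[s][t]:
                    total += npaths[s][i] * npaths[i][t] / npaths[s][t]
        betweenness[v] = total / norm
    return closeness, betweenness


# ---------------------------------------------------------------------------
# AUPR: average precision computed directly from the ranking
# ---------------------------------------------------------------------------


def manual_average_precision(labels, scores) -> float:
    """AP = sum over positives of precision at each positive's rank, with
    ties broken pessimistically the same way a stable descending sort does."""
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    tp = 0
    ap = 0.0
    n_pos = sum(labels)
    for rank, i in enumerate(order, start=1):
        if labels[i]:
            tp += 1
            ap += tp / rank
    return ap / n_pos
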