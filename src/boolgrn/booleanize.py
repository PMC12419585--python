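"""From continuous expression to executable Boolean rules.

Binarization assigns each gene's samples to ON/OFF by an exact 1-D
two-cluster split of the log-normalized values (the global minimizer of
within-cluster sum of squares, i.e. 1-D 2-means solved exactly over sorted
split points); the cluster with the higher center is ON.  Rule fitting then
learns, for a target and its directed parents, the truth table minimizing
the number of samples where the table output disagrees with the target's
binarized state ("best-fit extension"), with fully deterministic tie-breaks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .data import CountMatrix
from .network import BooleanNetwork
from .preprocessing import log_normalized


def _exact_two_means_threshold(values: np.ndarray) -> float | None:
    """Optimal 1-D 2-means split threshold, or None for constant input.

    Scans all n-1 sorted split points with prefix sums; returns the midpoint
    between the two boundary values of the best split (first minimal split on
    ties, so the result is deterministic).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 2 or x[0] == x[-1]:
        return None
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    total_sum, total_sq = csum[-1], csq[-1]
    k = np.arange(1, n)  # left cluster sizes
    left_ss = csq[:-1] - csum[:-1] ** 2 / k
    right_ss = (total_sq - csq[:-1]) - (total_sum - csum[:-1]) ** 2 / (n - k)
    best = int(np.argmin(left_ss + right_ss))
    return float((x[best] + x[best + 1]) / 2.0)


class TwoStateBinarizer(TransformerMixin, BaseEstimator):
    """Per-gene ON/OFF binarization of expression, sklearn-style.

    ``X`` is samples x genes.  ``method="kmeans2"`` uses the exact 1-D
    two-cluster split; ``method="mean_split"`` thresholds at the gene mean.
    Constant genes are flagged degenerate and map to all-OFF.

    Attributes
    ----------
    thresholds_ : per-gene split value (NaN for degenerate genes).
    degenerate_ : boolean mask of constant genes.
    """

    def __init__(self, method: str = "kmeans2"):
        self.method = method

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if self.method not in ("kmeans2", "mean_split"):
            raise ValueError(f"unknown method {self.method!r}")
        n_genes = X.shape[1]
        thr = np.full(n_genes, np.nan)
        degen = np.zeros(n_genes, dtype=bool)
        for j in range(n_genes):
            col = X[:, j]
            if col.min() == col.max():
                degen[j] = True
                continue
            if self.method == "kmeans2":
                thr[j] = _exact_two_means_threshold(col)
            else:
                thr[j] = col.mean()
        self.thresholds_ = thr
        self.degenerate_ = degen
        self.n_features_in_ = n_genes
        return self

    def transform(self, X):
        check_is_fitted(self, "thresholds_")
        X = check_array(X, dtype=float)
        out = np.zeros(X.shape, dtype=int)
        ok = ~self.degenerate_
        out[:, ok] = (X[:, ok] > self.thresholds_[ok]).astype(int)
        return out


def binarize(
    m: CountMatrix,
    factors: pd.Series | None = None,
    method: str = "kmeans2",
) -> tuple[pd.DataFrame, pd.Series]:
    """Binarize a count matrix on the log-normalized scale.

    Returns the genes x samples 0/1 state matrix and a per-gene boolean
    Series flagging degenerate (constant) genes, which are assigned all-OFF.
    """
    logx = log_normalized(m, factors)
    est = TwoStateBinarizer(method=method).fit(logx.to_numpy().T)
    states = pd.DataFrame(
        est.transform(logx.to_numpy().T).T, index=logx.index, columns=logx.columns
    )
    degenerate = pd.Series(est.degenerate_, index=logx.index, name="degenerate")
    return states, degenerate


def fit_boolean_rule(
    target: str,
    parents: list[str],
    states: pd.DataFrame,
    max_in_degree: int = 3,
) -> tuple[int, ...]:
    """Best-fit truth table for ``target`` given its parents.

    Minimizes the number of samples where the table applied to the parents'
    states disagrees with the target's state.  Because the error decomposes
    over input rows, each observed row independently takes the majority
    target value; ties and unobserved rows resolve to 0 — which realizes the
    global tie-break (fewest ON outputs, then lexicographically smallest
    table).  Row order is binary counting over parents in listed order, first
    parent most significant.
    """
    if len(parents) > max_in_degree:
        raise ValueError(
            f"{len(parents)} parents exceed the in-degree cap {max_in_degree}"
        )
    if states.shape[1] < 1:
        raise ValueError("need at least one sample")
    k = len(parents)
    y = states.loc[target].to_numpy()
    if k == 0:
        ones = int(y.sum())
        return (1 if ones > y.size - ones else 0,)
    P = states.loc[parents].to_numpy()  # k x samples
    rows = np.zeros(states.shape[1], dtype=int)
    for bits in P:
        rows = (rows << 1) | bits
    table = []
    for r in range(2 ** k):
        sel = rows == r
        ones = int(y[sel].sum())
        zeros = int(sel.sum()) - ones
        table.append(1 if ones > zeros else 0)
    return tuple(table)


def rule_errors(table: tuple[int, ...], parents: list[str], target: str,
                states: pd.DataFrame) -> int:
    """Number of samples where the table's output disagrees with the target."""
    k = len(parents)
    y = states.loc[target].to_numpy()
    if k == 0:
        return int(np.sum(y != table[0]))
    rows = np.zeros(states.shape[1], dtype=int)
    for bits in states.loc[parents].to_numpy():
        rows = (rows << 1) | bits
    pred = np.asarray(table)[rows]
    return int(np.sum(pred != y))


def fit_network_rules(
    graph: nx.DiGraph,
    states: pd.DataFrame,
    max_in_degree: int = 3,
) -> BooleanNetwork:
    """Fit best-fit rules for every node of a directed parent structure.

    Parents of each gene are its incoming edges ordered by descending weight
    (name-alphabetical on ties) and truncated to ``max_in_degree``; gene
    order follows the state matrix.  Genes absent from the graph's edge set
    become majority-vote constants.
    """
    missing = sorted(set(graph.nodes) - set(states.index))
    if missing:
        raise KeyError(f"graph nodes missing from state matrix: {missing[:5]}")
    genes = [g for g in states.index if g in graph.nodes]
    parents: dict[str, list[str]] = {}
    tables: dict[str, tuple[int, ...]] = {}
    for g in genes:
        incoming = sorted(
            graph.in_edges(g, data=True),
            key=lambda e: (-e[2].get("weight", 0.0), e[0]),
        )
        ps = [u for u, _, _ in incoming[:max_in_degree]]
        parents[g] = ps
        tables[g] = fit_boolean_rule(g, ps, states, max_in_degree=max_in_degree)
    return BooleanNetwork(genes=genes, parents=parents, truth_tables=tables)
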