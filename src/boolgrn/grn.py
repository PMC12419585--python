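"""GENIE3-style directed network inference from expression profiles.

For each target gene a random-forest regression predicts the target's
standardized expression from all other candidate genes; the importance of a
regulator is the total impurity (variance) reduction attributed to splits on
it, summed over trees and normalized per target.  Ranking all
regulator->target pairs by importance and thresholding yields a directed
weighted gene network.

Defaults follow the original GENIE3 publication: 1000 trees and sqrt(p)
candidate features per split.  Per-target sub-seeds are derived
deterministically from (seed, target index), so results do not depend on the
order targets happen to be fitted in.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import average_precision_score
from sklearn.utils.validation import check_array, check_is_fitted

from .data import CountMatrix
from .preprocessing import log_normalized


class GENIE3(BaseEstimator):
    """Tree-ensemble regulatory-network inference, sklearn-style.

    ``fit(X)`` takes samples x genes expression (any monotone scale; each
    gene is standardized internally).  The fitted ``importances_`` matrix has
    ``importances_[r, t]`` = importance of regulator ``r`` for target ``t``,
    normalized to sum to 1 over regulators for every non-degenerate target.

    Parameters
    ----------
    n_trees : trees per target ensemble.
    k_features : features considered per split ("sqrt", "all", or an int).
    seed : master seed; per-target seeds are spawned from it.
    """

    def __init__(self, n_trees: int = 1000, k_features="sqrt", seed: int = 0):
        self.n_trees = n_trees
        self.k_features = k_features
        self.seed = seed

    def _max_features(self):
        if self.k_features == "sqrt":
            return "sqrt"
        if self.k_features == "all":
            return 1.0
        return int(self.k_features)

    def fit(self, X, y=None, feature_names=None):
        X = check_array(X, dtype=float)
        n_samples, n_genes = X.shape
        if n_samples < 3:
            raise ValueError("need >= 3 samples")
        if n_genes < 3:
            raise ValueError("need >= 2 candidate regulators per target")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

        # moments taken over sorted columns so the standardized values are
        # bit-identical under any sample permutation (summation order fixed)
        Xs = np.sort(X, axis=0)
        sd = Xs.std(axis=0)
        mu = Xs.mean(axis=0)
        Z = np.zeros_like(X)
        ok = sd > 0
        Z[:, ok] = (X[:, ok] - mu[ok]) / sd[ok]

        imp = np.zeros((n_genes, n_genes))
        degenerate = []
        for t in range(n_genes):
            if not ok[t]:
                degenerate.append(t)  # constant target: zero row, flagged
                continue
            regs = np.delete(np.arange(n_genes), t)
            sub_seed = int(
                np.random.SeedSequence([self.seed, t]).generate_state(1)[0] % (2**31)
            )
            # bootstrap off: every tree sees all samples, so importances are
            # invariant to sample order; randomness enters only through the
            # per-split feature subsampling
            forest = RandomForestRegressor(
                n_estimators=self.n_trees,
                max_features=self._max_features(),
                bootstrap=False,
                random_state=sub_seed,
                n_jobs=1,
            )
            forest.fit(Z[:, regs], Z[:, t])
            imp[regs, t] = forest.feature_importances_
            total = imp[:, t].sum()
            if total > 0:
                imp[:, t] /= total

        self.importances_ = imp
        self.feature_names_ = (
            list(feature_names)
            if feature_names is not None
            else [f"g{i}" for i in range(n_genes)]
        )
        self.degenerate_targets_ = [self.feature_names_[t] for t in degenerate]
        self.n_features_in_ = n_genes
        return self

    def to_graph(self) -> nx.DiGraph:
        """Complete weighted digraph of all regulator->target importances."""
        check_is_fitted(self, "importances_")
        g = nx.DiGraph()
        g.add_nodes_from(self.feature_names_)
        n = len(self.feature_names_)
        for r in range(n):
            for t in range(n):
                if r != t:
                    g.add_edge(
                        self.feature_names_[r],
                        self.feature_names_[t],
                        weight=float(self.importances_[r, t]),
                    )
        return g


def genie3_importances(
    m: CountMatrix,
    candidates: list[str] | None = None,
    n_trees: int = 1000,
    k_features="sqrt",
    seed: int = 0,
) -> nx.DiGraph:
    """Infer the complete importance digraph from a count matrix.

    Expression is log2-normalized before fitting; ``candidates`` restricts
    both regulators and targets to a gene subset (e.g. a circadian gene set).
    """
    sub = m.subset_genes(list(candidates)) if candidates is not None else m
    logx = log_normalized(sub)
    est = GENIE3(n_trees=n_trees, k_features=k_features, seed=seed)
    est.fit(logx.to_numpy().T, feature_names=list(logx.index))
    return est.to_graph()


def threshold_edges(
    g: nx.DiGraph, mode: str, value: float, keep_isolated: bool = False
) -> nx.DiGraph:
    """Keep only edges passing a threshold rule.

    Modes: ``weight_min`` (weight >= value), ``top_k_edges`` (the k largest
    weights globally), ``top_k_per_target`` (the k strongest incoming edges
    of every target).  Nodes left without any edge are dropped unless
    ``keep_isolated``.
    """
    if value < 0:
        raise ValueError("threshold value must be >= 0")
    edges = [(u, v, d.get("weight", 0.0)) for u, v, d in g.edges(data=True)]
    if mode == "weight_min":
        kept = [(u, v, w) for u, v, w in edges if w >= value]
    elif mode == "top_k_edges":
        k = int(value)
        kept = sorted(edges, key=lambda e: (-e[2], e[0], e[1]))[:k]
    elif mode == "top_k_per_target":
        k = int(value)
        by_target: dict[str, list] = {}
        for u, v, w in edges:
            by_target.setdefault(v, []).append((u, v, w))
        kept = []
        for v in sorted(by_target):
            kept.extend(
                sorted(by_target[v], key=lambda e: (-e[2], e[0]))[:k]
            )
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")

    out = nx.DiGraph()
    if keep_isolated:
        out.add_nodes_from(g.nodes)
    for u, v, w in kept:
        out.add_edge(u, v, weight=w)
    return out


def edge_aupr(g: nx.DiGraph, true_edges: set[tuple[str, str]]) -> float:
    """Area under the precision-recall curve of the edge ranking.

    Every ordered gene pair (r, t), r != t, is a hypothesis scored by its
    importance (0 if absent from the graph); ``true_edges`` is the planted
    regulator->target edge list.
    """
    nodes = sorted(g.nodes)
    scores, labels = [], []
    for r in nodes:
        for t in nodes:
            if r == t:
                continue
            scores.append(g[r][t]["weight"] if g.has_edge(r, t) else 0.0)
            labels.append(1 if (r, t) in true_edges else 0)
    if not any(labels):
        raise ValueError("no true edge falls among the scored pairs")
    return float(average_precision_score(labels, scores))


def edge_prevalence(n_nodes: int, n_true_edges: int) -> float:
    """Fraction of the n(n-1) ordered pairs that are true edges (the AUPR of
    a random ranking, in expectation)."""
    return n_true_edges / (n_nodes * (n_nodes - 1))


def network_edges(net) -> set[tuple[str, str]]:
    """Planted parent->child edge set of a BooleanNetwork."""
    return {(p, g) for g in net.genes for p in net.parents[g]}


def write_edge_list(g: nx.DiGraph, path) -> None:
    rows = [
        {"regulator": u, "target": v, "weight": d.get("weight", 0.0)}
        for u, v, d in g.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["regulator", "target", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def read_edge_list(path) -> nx.DiGraph:
    df = pd.read_csv(path, sep="\t")
    g = nx.DiGraph()
    for _, row in df.iterrows():
        g.add_edge(row["regulator"], row["target"], weight=float(row["weight"]))
    return g
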