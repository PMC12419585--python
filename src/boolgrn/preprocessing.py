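"""Sequencing-depth normalization and variance diagnostics.

Normalization uses the median-of-ratios estimator: each sample's size factor
is the median, over genes with strictly positive counts in every sample, of
the ratio of that gene's count to its across-sample geometric mean.  Dividing
counts by the factors makes samples of different sequencing depth comparable.
Log transforms throughout the package are ``log2(normalized + 1)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .data import CountMatrix


class NormalizationError(ValueError):
    """No gene qualifies for the geometric-mean reference."""


class MedianOfRatiosNormalizer(TransformerMixin, BaseEstimator):
    """Median-of-ratios size-factor normalization, sklearn-style.

    Follows the sklearn orientation: ``X`` is samples x genes.  ``fit``
    estimates one positive size factor per sample; ``transform`` divides each
    sample's counts by its factor.

    Size factors are only identified relative to the per-gene reference:
    re-estimating the reference after rescaling one sample rescales every
    factor by a common constant, while a fixed ``reference`` (e.g. the
    geometric means of a baseline cohort) makes the factors exactly
    equivariant — scaling a sample's counts by c scales its factor by c and
    leaves the others untouched.

    Parameters
    ----------
    reference : ndarray of per-gene geometric means, optional
        If given, ratios are taken against this fixed reference (entries that
        are NaN or non-positive are excluded); otherwise the reference is the
        geometric mean over the fitted samples, restricted to genes with
        strictly positive counts everywhere.

    Attributes
    ----------
    size_factors_ : ndarray of shape (n_samples,)
        Estimated per-sample factors.
    reference_ : ndarray of shape (n_genes,)
        The per-gene reference used (NaN for excluded genes).
    """

    def __init__(self, reference=None):
        self.reference = reference

    def fit(self, X, y=None):
        X = check_array(X, dtype=float, ensure_min_samples=1)
        if (X < 0).any():
            raise ValueError("counts must be non-negative")
        if self.reference is not None:
            ref = np.asarray(self.reference, dtype=float)
            if ref.shape != (X.shape[1],):
                raise ValueError("reference must have one entry per gene")
            use = np.isfinite(ref) & (ref > 0)
        else:
            ref = np.full(X.shape[1], np.nan)
            use = (X > 0).all(axis=0)
            if use.any():
                ref[use] = np.exp(np.log(X[:, use]).mean(axis=0))
        if not use.any():
            raise NormalizationError(
                "cannot normalize: no gene has strictly positive counts "
                "in every sample"
            )
        ratios = X[:, use] / ref[use]
        self.size_factors_ = np.median(ratios, axis=1)
        self.reference_ = np.where(use, ref, np.nan)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "size_factors_")
        X = check_array(X, dtype=float)
        if X.shape[0] != self.size_factors_.shape[0]:
            raise ValueError("transform expects the same samples as fit")
        return X / self.size_factors_[:, None]


def size_factors(m: CountMatrix, reference: pd.Series | None = None) -> pd.Series:
    """Per-sample median-of-ratios size factors for a count matrix.

    ``reference`` optionally fixes the per-gene geometric-mean reference
    (indexed by gene) instead of re-estimating it from ``m``.
    """
    ref = None
    if reference is not None:
        ref = reference.reindex(m.genes).to_numpy(dtype=float)
    est = MedianOfRatiosNormalizer(reference=ref).fit(m.counts.to_numpy().T)
    return pd.Series(est.size_factors_, index=m.samples, name="size_factor")


def geometric_mean_reference(m: CountMatrix) -> pd.Series:
    """Per-gene geometric means over samples (NaN where any count is zero)."""
    est = MedianOfRatiosNormalizer().fit(m.counts.to_numpy().T)
    return pd.Series(est.reference_, index=m.genes, name="reference")


def normalized_counts(m: CountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts divided by per-sample size factors (genes x samples)."""
    if factors is None:
        factors = size_factors(m)
    factors = factors.reindex(m.samples)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("size factors must be positive and cover all samples")
    return m.counts / factors


def log_normalized(m: CountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    """``log2(normalized + 1)`` expression values (genes x samples)."""
    return np.log2(normalized_counts(m, factors) + 1.0)


def mean_sd_trend(m: CountMatrix, window: int = 101) -> pd.DataFrame:
    """Per-gene mean and SD of log-normalized expression with a running-median
    trend.

    Genes are rank-ordered by mean; the trend at each gene is the median SD
    within a centred window of that many genes (truncated at the ends).
    Returned as a DataFrame with columns ``mean``, ``sd``, ``trend`` indexed
    by gene, sorted by mean — ready for a mean-SD diagnostic plot.
    """
    if window < 3:
        raise ValueError("window must be >= 3")
    logx = log_normalized(m)
    if logx.shape[0] < window:
        raise ValueError(f"need at least {window} genes for window={window}")
    stats = pd.DataFrame(
        {"mean": logx.mean(axis=1), "sd": logx.std(axis=1, ddof=1)}
    ).sort_values("mean", kind="mergesort")
    sd = stats["sd"].to_numpy()
    half = window // 2
    trend = np.empty_like(sd)
    for i in range(len(sd)):
        lo, hi = max(0, i - half), min(len(sd), i + half + 1)
        trend[i] = np.median(sd[lo:hi])
    stats["trend"] = trend
    return stats
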