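"""Two-group differential expression with an empirical-Bayes moderated t.

Per gene, on log2-normalized expression: group means, pooled residual
variance s^2 with d = n1 + n2 - 2 degrees of freedom.  Across genes the
variances are modelled as s^2 ~ s0^2 * F(d, d0); the prior degrees of
freedom d0 and prior variance s0^2 are fit by method of moments on
z = log s^2 (matching the scaled-F moments via digamma/trigamma), giving the
posterior variance

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

and the moderated statistic t = (mean_treated - mean_control) /
(s_tilde * sqrt(1/n1 + 1/n2)), referred to a t distribution with d0 + d
degrees of freedom.  Shrinking each gene's variance toward the common prior
stabilizes inference at the very small group sizes (4 vs 4) this design has.

Genes are then gated into up / down / ns classes by a p-value threshold and
a symmetric log-fold-change cut (defaults 0.05 and 1.5).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .data import TREATED, CountMatrix
from .preprocessing import log_normalized

_D0_MIN, _D0_MAX = 0.01, 1e6


def _inverse_trigamma(y: float, tol: float = 1e-12, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + step
        if abs(step) < tol * x:
            break
    return float(x)


def fit_f_dist_moments(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) for s^2 ~ s0^2 F(df, d0).

    Works on z = log s^2: Var(z) = trigamma(df/2) + trigamma(d0/2) and
    E(z) = log s0^2 + [digamma(df/2) - log(df/2)] - [digamma(d0/2) - log(d0/2)].
    Genes with zero variance are excluded from the fit.  An infinite d0
    estimate (observed spread no larger than the chi-square expectation) is
    clipped to a large finite value so downstream t degrees of freedom stay
    defined.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        raise ValueError("need >= 2 genes with positive variance for the EB fit")
    z = np.log(s2)
    evar = z.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _inverse_trigamma(evar)
    else:
        d0 = np.inf
    d0 = float(np.clip(d0, _D0_MIN, _D0_MAX))
    log_s0 = (
        z.mean()
        - special.digamma(df / 2.0)
        + np.log(df / 2.0)
        + special.digamma(d0 / 2.0)
        - np.log(d0 / 2.0)
    )
    return d0, float(np.exp(log_s0))


class ModeratedTTest(BaseEstimator):
    """Moderated two-sample t test over many genes, sklearn-style.

    ``fit(X, y)`` takes ``X`` as samples x genes log-expression and binary
    labels ``y``; the contrast is ``treated_label`` minus the other group.

    Parameters
    ----------
    alpha, fc_cut, use_adjusted
        Gates for the up/down/ns classification (p below ``alpha`` and
        |log2 fold change| above ``fc_cut``; ``use_adjusted`` gates on the
        BH-adjusted p instead of the raw p).
    d0_override
        ``None`` fits the prior df by moments; ``0`` disables shrinkage
        (ordinary pooled t); ``numpy.inf`` forces full shrinkage to s0^2.

    Attributes
    ----------
    log_fc_, t_, p_value_, p_adjusted_ : ndarray per gene
    df_prior_, s2_prior_ : the empirical-Bayes hyperparameters (d0, s0^2)
    df_residual_ : pooled residual df d
    df_total_ : d0 + d, the moderated t's degrees of freedom
    """

    def __init__(
        self,
        alpha: float = 0.05,
        fc_cut: float = 1.5,
        use_adjusted: bool = False,
        d0_override: float | None = None,
        treated_label=TREATED,
    ):
        self.alpha = alpha
        self.fc_cut = fc_cut
        self.use_adjusted = use_adjusted
        self.d0_override = d0_override
        self.treated_label = treated_label

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be samples x genes with one label per sample")
        treated = y == self.treated_label
        n1, n2 = int((~treated).sum()), int(treated.sum())
        if n1 < 2 or n2 < 2:
            raise ValueError("need >= 2 samples per group")
        d = n1 + n2 - 2
        if d <= 0:
            raise ValueError("zero residual degrees of freedom")

        xc, xt = X[~treated], X[treated]
        mc, mt = xc.mean(axis=0), xt.mean(axis=0)
        ssq = ((xc - mc) ** 2).sum(axis=0) + ((xt - mt) ** 2).sum(axis=0)
        s2 = ssq / d

        # degenerate data (fewer than 2 genes with positive variance) cannot
        # identify the prior; fall back to full shrinkage toward the mean s2
        can_fit = int((s2 > 0).sum()) >= 2
        if self.d0_override is None:
            if can_fit:
                d0, s0_sq = fit_f_dist_moments(s2, d)
            else:
                d0, s0_sq = _D0_MAX, float(np.mean(s2))
        elif self.d0_override == 0:
            d0 = 0.0
            s0_sq = float(np.mean(s2[s2 > 0])) if (s2 > 0).any() else 0.0
        elif np.isinf(self.d0_override):
            s0_sq = fit_f_dist_moments(s2, d)[1] if can_fit else float(np.mean(s2))
            d0 = np.inf
        else:
            d0 = float(np.clip(self.d0_override, _D0_MIN, _D0_MAX))
            s0_sq = fit_f_dist_moments(s2, d)[1] if can_fit else float(np.mean(s2))

        if np.isinf(d0):
            post = np.full_like(s2, s0_sq)
            df_total = _D0_MAX + d
        else:
            post = (d0 * s0_sq + d * s2) / (d0 + d)
            df_total = d0 + d

        delta = mt - mc
        se = np.sqrt(post * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = delta / se
        t = np.where((delta == 0) & (se == 0), 0.0, t)
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
        p = np.clip(p, np.nextafter(0, 1), 1.0)

        self.log_fc_ = delta
        self.t_ = t
        self.p_value_ = p
        self.p_adjusted_ = multipletests(p, method="fdr_bh")[1]
        self.df_prior_ = d0
        self.s2_prior_ = s0_sq
        self.s2_posterior_ = post
        self.df_residual_ = d
        self.df_total_ = df_total
        self.n_features_in_ = X.shape[1]
        return self

    def results_(self, genes=None) -> pd.DataFrame:
        check_is_fitted(self, "t_")
        table = pd.DataFrame(
            {
                "log2FC": self.log_fc_,
                "t": self.t_,
                "p": self.p_value_,
                "p_adj": self.p_adjusted_,
            },
            index=genes if genes is not None else pd.RangeIndex(len(self.t_)),
        )
        return classify_degs(
            table, alpha=self.alpha, fc_cut=self.fc_cut, use_adjusted=self.use_adjusted
        )


def moderated_t(
    m: CountMatrix,
    factors: pd.Series | None = None,
    alpha: float = 0.05,
    fc_cut: float = 1.5,
    use_adjusted: bool = False,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Moderated-t DE table (gene, log2FC, t, p, p_adj, class) for a count
    matrix; log2FC is treated (HFD) minus control (ND) on log2-normalized
    values."""
    logx = log_normalized(m, factors)
    est = ModeratedTTest(
        alpha=alpha, fc_cut=fc_cut, use_adjusted=use_adjusted, d0_override=d0_override
    ).fit(logx.to_numpy().T, m.condition.to_numpy())
    table = est.results_(genes=logx.index)
    table.index.name = "gene"
    return table


def classify_degs(
    table: pd.DataFrame,
    alpha: float = 0.05,
    fc_cut: float = 1.5,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Assign up / down / ns classes by the significance and fold-change gates.

    A gene is ``up`` when its (raw or adjusted) p-value is below ``alpha``
    and log2FC exceeds ``fc_cut``, ``down`` when p is below ``alpha`` and
    log2FC falls below ``-fc_cut``, otherwise ``ns``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if fc_cut < 0:
        raise ValueError("fc_cut must be >= 0")
    p = table["p_adj"] if use_adjusted else table["p"]
    lfc = table["log2FC"]
    cls = np.where(
        (p < alpha) & (lfc > fc_cut),
        "up",
        np.where((p < alpha) & (lfc < -fc_cut), "down", "ns"),
    )
    out = table.copy()
    out["class"] = cls
    return out
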