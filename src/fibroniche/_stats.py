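"""Shared statistical primitives: BH-FDR, logit proportions, empirical-Bayes
variance moderation and the mean-variance (voom-style) weight trend.

The moderation follows the standard hierarchical model for feature-wise
variances: s_g^2 | sigma_g^2 ~ sigma_g^2 * chi^2_{d_g} / d_g with a scaled
inverse-chi-square prior sigma_g^2 ~ s_0^2 * d_0 / chi^2_{d_0}. The prior
(d_0, s_0^2) is fitted by matching moments of log s_g^2 (digamma/trigamma
closed forms) and the posterior variance is the precision-weighted blend
(d_0 s_0^2 + d_g s_g^2) / (d_0 + d_g).
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

__all__ = ["bh_fdr", "logit_proportions", "squeeze_var", "lowess_sqrt_sd_trend"]


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1).

    NaN inputs propagate to NaN and are excluded from the ranking.
    """
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def logit_proportions(counts: np.ndarray, pseudocount: float = 0.5) -> np.ndarray:
    """Logit-transformed row proportions with a moderated pseudocount.

    ``counts`` is a sample x feature matrix; ``pseudocount`` is added to each
    count before forming proportions so zero counts map to a finite logit.
    """
    c = np.asarray(counts, dtype=float) + pseudocount
    p = c / c.sum(axis=1, keepdims=True)
    return np.log(p / (1.0 - p))


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration (limma's approach)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x  # good starting value for trigamma inverse
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if np.all(np.abs(dif) < 1e-10 * y):
            break
    return y


def squeeze_var(s2: np.ndarray, df: float | np.ndarray) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes moderation of feature-wise variances.

    Returns ``(s2_post, df_prior, s2_prior)``. With an infinite fitted prior
    df all variances shrink to the common value. Features with zero residual
    df take the prior variance.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape).copy()
    ok = (df > 0) & np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        prior = float(np.nanmean(s2[ok])) if ok.any() else 1.0
        return np.where(ok, s2, prior), np.inf, prior

    z = np.log(s2[ok])
    e = z - special.digamma(df[ok] / 2.0) + np.log(df[ok] / 2.0)
    emean = e.mean()
    evar = np.var(e, ddof=1) - np.mean(special.polygamma(1, df[ok] / 2.0))
    if evar <= 0:
        df0 = np.inf
        s20 = float(np.exp(emean))
    else:
        df0 = float(2.0 * _trigamma_inverse(np.array([evar]))[0])
        s20 = float(np.exp(emean + special.digamma(df0 / 2.0) - np.log(df0 / 2.0)))

    post = np.empty_like(s2)
    if np.isinf(df0):
        post[:] = s20
    else:
        post = (df0 * s20 + df * np.where(ok, s2, 0.0)) / (df0 + df)
        post[df <= 0] = s20
    return post, df0, s20


def lowess_sqrt_sd_trend(mean_log: np.ndarray, sqrt_sd: np.ndarray, frac: float = 0.5):
    """Lowess trend of sqrt residual standard deviation against mean
    log-expression; returns an interpolator clipped to the fitted range."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    fit = lowess(sqrt_sd, mean_log, frac=frac, return_sorted=True)
    xs, ys = fit[:, 0], np.maximum(fit[:, 1], 1e-6)

    def interp(x: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(x, dtype=float), xs, ys)

    return interp


def ks_uniform_pvalue(p: np.ndarray) -> float:
    """Kolmogorov-Smirnov p-value against Uniform(0, 1)."""
    p = np.asarray(p, dtype=float)
    p = p[~np.isnan(p)]
    return float(stats.kstest(p, "uniform").pvalue)
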