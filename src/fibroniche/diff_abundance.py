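"""Proportion- and expression-level differential analyses.

Cell-type / niche / gene composition is analysed on logit-transformed
per-sample proportions (counts get a 0.5 pseudocount so zeros stay finite),
with ordinary linear models per feature and empirical-Bayes moderation of the
residual variances across features (scaled inverse-chi-square prior fitted by
moments). Pseudobulk differential expression across annotated pathology
features uses log2(CPM + 0.5 pseudocount), a low-expression filter, a
mean-variance (voom-style) lowess trend supplying per-observation weights,
weighted linear models with a TMA batch covariate and moderated t statistics.
All multiple-testing correction is Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from ._stats import bh_fdr, logit_proportions, lowess_sqrt_sd_trend, squeeze_var
from .preprocess import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "logit_prop_anova",
    "logit_prop_trend",
    "niche_representative_genes",
    "gene_eligibility_per_celltype",
    "pseudobulk_de",
]


def _design_groups(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    levels = np.asarray(sorted(pd.unique(groups)))
    X = (groups[:, None] == levels[None, :]).astype(float)
    return X, levels


def logit_prop_anova(counts: pd.DataFrame, groups, pseudocount: float = 0.5) -> pd.DataFrame:
    """Test per-feature proportion differences among groups (moderated F).

    ``counts`` is a sample x feature count table (rows are converted to
    proportions with a pseudocount before the logit transform); ``groups``
    assigns each sample to a disease group. Features absent in every sample
    are skipped. Returns one row per tested feature with F, p and FDR.
    """
    groups = np.asarray(groups)
    if len(groups) != len(counts):
        raise ValueError("groups must align with count rows")
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    for g in levels:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has < 2 samples")

    present = counts.to_numpy().sum(axis=0) > 0
    if not present.all():
        logger.info("skipping %d features absent in all samples", int((~present).sum()))
    feats = counts.columns.to_numpy()[present]
    Y = logit_proportions(counts.to_numpy(), pseudocount)[:, present]

    X, _ = _design_groups(groups)
    n, g = X.shape
    H = X @ np.linalg.pinv(X)
    resid = Y - H @ Y
    rss1 = (resid**2).sum(axis=0)
    df_res = n - g
    rss0 = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)

    s2 = rss1 / df_res
    s2_post, df0, _ = squeeze_var(s2, df_res)
    df_num = g - 1
    F = (rss0 - rss1) / df_num / s2_post
    from scipy import stats

    df_den = df_res + (df0 if np.isfinite(df0) else 0.0)
    if np.isinf(df0):
        p = stats.chi2.sf(F * df_num, df_num)
    else:
        p = stats.f.sf(F, df_num, df_den)
    return pd.DataFrame(
        {"feature": feats, "F": F, "p_value": p, "fdr": bh_fdr(p)}
    ).sort_values("p_value", kind="mergesort").reset_index(drop=True)


def logit_prop_trend(
    counts: pd.DataFrame,
    covariate,
    pseudocount: float = 0.5,
    min_prop: float | None = 5e-4,
) -> pd.DataFrame:
    """Per-feature linear trend of logit proportions against a continuous
    covariate (percent pathology), with moderated t statistics.

    When ``min_prop`` is set, a sample is excluded from a feature's test if
    its (pseudocounted) proportion of that feature falls below the threshold
    — samples contributing only a few stray transcripts to a niche carry no
    signal about it.
    """
    x = np.asarray(covariate, dtype=float)
    if len(x) != len(counts):
        raise ValueError("covariate must align with count rows")
    C = counts.to_numpy(dtype=float) + pseudocount
    P = C / C.sum(axis=1, keepdims=True)
    Y = np.log(P / (1 - P))

    feats = counts.columns.to_numpy()
    slope = np.full(len(feats), np.nan)
    s2 = np.full(len(feats), np.nan)
    df = np.zeros(len(feats))
    vb = np.full(len(feats), np.nan)  # unscaled slope variance
    for j in range(len(feats)):
        use = np.ones(len(x), dtype=bool) if min_prop is None else P[:, j] >= min_prop
        if use.sum() < 3 or np.ptp(x[use]) == 0:
            continue
        X = np.column_stack([np.ones(use.sum()), x[use]])
        b, *_ = np.linalg.lstsq(X, Y[use, j], rcond=None)
        r = Y[use, j] - X @ b
        d = use.sum() - 2
        slope[j] = b[1]
        s2[j] = (r @ r) / d
        df[j] = d
        vb[j] = np.linalg.inv(X.T @ X)[1, 1]

    ok = df > 0
    s2_post, df0, _ = squeeze_var(s2[ok], df[ok])
    from scipy import stats

    t = np.full(len(feats), np.nan)
    p = np.full(len(feats), np.nan)
    t[ok] = slope[ok] / np.sqrt(s2_post * vb[ok])
    df_tot = df[ok] + (df0 if np.isfinite(df0) else 0.0)
    if np.isinf(df0):
        p[ok] = 2 * stats.norm.sf(np.abs(t[ok]))
    else:
        p[ok] = 2 * stats.t.sf(np.abs(t[ok]), df_tot)
    return pd.DataFrame(
        {"feature": feats, "slope": slope, "t": t, "n_used": df + 2, "p_value": p, "fdr": bh_fdr(p)}
    ).sort_values("p_value", kind="mergesort").reset_index(drop=True)


def niche_representative_genes(
    t: pd.DataFrame,
    niche_col: str = "transcript_niche",
    min_niche_prop: float = 5e-4,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Representative genes of each transcript niche.

    ``t`` holds labeled, quality-filtered transcripts (``sample_id``,
    ``feature_name`` and a niche label column). Within each sample and niche,
    gene proportions are logit-transformed; a per-gene linear model with
    sample and niche effects contrasts each niche's mean against the average
    of the other niches. Samples contributing a niche share below
    ``min_niche_prop`` are excluded from that niche. FDR is computed across
    genes within each niche.
    """
    genes = np.asarray(sorted(t["feature_name"].unique()))
    units = []
    for (sid, niche), sub in t.groupby(["sample_id", niche_col], sort=True):
        share = len(sub) / (t["sample_id"] == sid).sum()
        if share < min_niche_prop:
            logger.info("sample %s excluded for niche %s (share %.2e)", sid, niche, share)
            continue
        cnt = sub["feature_name"].value_counts().reindex(genes).fillna(0.0).to_numpy()
        units.append((sid, niche, cnt))
    if not units:
        raise ValueError("no (sample, niche) units to test")
    niches = np.asarray(sorted({u[1] for u in units}))
    if len(niches) < 2:
        raise ValueError("need >= 2 niches")
    samples = np.asarray(sorted({u[0] for u in units}))

    C = np.stack([u[2] for u in units]) + pseudocount
    P = C / C.sum(axis=1, keepdims=True)
    Y = np.log(P / (1 - P))
    u_niche = np.array([u[1] for u in units])
    u_sample = np.array([u[0] for u in units])

    # one-hot niche means + sample effects (first sample absorbed)
    Xn = (u_niche[:, None] == niches[None, :]).astype(float)
    Xs = (u_sample[:, None] == samples[None, 1:]).astype(float)
    X = np.hstack([Xn, Xs])
    XtXi = np.linalg.pinv(X.T @ X)
    B = XtXi @ X.T @ Y
    resid = Y - X @ B
    df_res = len(units) - np.linalg.matrix_rank(X)
    s2 = (resid**2).sum(axis=0) / max(df_res, 1)
    s2_post, df0, _ = squeeze_var(s2, df_res)
    from scipy import stats

    rows = []
    k = len(niches)
    for i, niche in enumerate(niches):
        c = np.zeros(X.shape[1])
        c[:k] = -1.0 / (k - 1)
        c[i] = 1.0
        eff = c @ B
        v = float(c @ XtXi @ c)
        tstat = eff / np.sqrt(s2_post * v)
        df_tot = df_res + (df0 if np.isfinite(df0) else 0.0)
        p = 2 * (stats.norm.sf(np.abs(tstat)) if np.isinf(df0) else stats.t.sf(np.abs(tstat), df_tot))
        rows.append(pd.DataFrame({
            "niche": niche, "gene": genes, "effect": eff, "t": tstat,
            "p_value": p, "fdr": bh_fdr(p),
        }))
    return pd.concat(rows, ignore_index=True)


def gene_eligibility_per_celltype(
    m: CountMatrix,
    cell_types: pd.Series | np.ndarray,
    min_count: float = 5.0,
    min_cell_fraction: float = 0.3,
    scale: float = 1000.0,
    min_cells: int = 10,
) -> dict[str, np.ndarray]:
    """Per-cell-type boolean gene masks for contamination-aware DE.

    Counts are scaled per cell to counts-per-1K; a gene is eligible within a
    cell type when at least ``min_cell_fraction`` of that type's cells show
    >= ``min_count`` scaled counts. Genes a type merely borrows from
    spillover fail this within-type prevalence bar. Types with fewer than
    ``min_cells`` cells get an all-false mask, with a warning.
    """
    ct = np.asarray(cell_types)
    if len(ct) != m.shape[0]:
        raise ValueError("cell_types must align with matrix rows")
    totals = np.maximum(m.totals, 1.0)
    masks: dict[str, np.ndarray] = {}
    for t in sorted(pd.unique(ct)):
        idx = np.flatnonzero(ct == t)
        if len(idx) < min_cells:
            warnings.warn(f"cell type {t!r} has {len(idx)} cells (<{min_cells}); empty mask", stacklevel=2)
            masks[t] = np.zeros(m.shape[1], dtype=bool)
            continue
        sub = m.X[idx].multiply(scale / totals[idx][:, None]).tocsc()
        n_hit = np.asarray((sub >= min_count).sum(axis=0)).ravel()
        masks[t] = n_hit >= min_cell_fraction * len(idx)
    return masks


def pseudobulk_de(
    pb: pd.DataFrame,
    annotation: pd.Series | np.ndarray,
    tma: pd.Series | np.ndarray | None = None,
    min_log2cpm: float = 8.0,
    max_low_fraction: float = 0.5,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Voom-style weighted one-vs-rest DE across annotation instances.

    ``pb`` is a unit x gene table of aggregated counts (one row per
    annotation instance). Expression becomes log2 CPM with a 0.5 pseudocount;
    genes below ``min_log2cpm`` in at least ``max_low_fraction`` of units are
    excluded. A lowess trend of sqrt residual standard deviation against mean
    log2 count converts fitted values into per-observation precision weights;
    weighted linear models (one-vs-rest indicator + optional TMA covariate)
    with moderated t statistics yield one table row per (annotation type,
    gene). Contrasts with a single unit on either side are refused.
    """
    annotation = np.asarray(annotation)
    counts = pb.to_numpy(dtype=float)
    lib = counts.sum(axis=1)
    if np.any(lib <= 0):
        raise ValueError("every unit needs a positive library size")
    log2cpm = np.log2((counts + pseudocount) / (lib + 1.0)[:, None] * 1e6)
    low = (log2cpm < min_log2cpm).mean(axis=0) >= max_low_fraction
    genes = pb.columns.to_numpy()[~low]
    Y = log2cpm[:, ~low]
    logger.info("pseudobulk DE: %d/%d genes pass the expression filter", len(genes), pb.shape[1])
    if len(genes) == 0:
        raise ValueError("no genes pass the low-expression filter")

    n = len(annotation)
    covs = [np.ones(n)]
    if tma is not None:
        tma = np.asarray(tma)
        for lv in sorted(pd.unique(tma))[1:]:
            covs.append((tma == lv).astype(float))
    base = np.column_stack(covs)

    # voom-style weights from an unweighted first pass over all contrasts' shared
    # null design (intercept + batch): trend of sqrt-sd vs mean log2 count
    H = base @ np.linalg.pinv(base)
    resid0 = Y - H @ Y
    df0_res = n - np.linalg.matrix_rank(base)
    sd = np.sqrt((resid0**2).sum(axis=0) / max(df0_res, 1))
    mean_log2cpm = Y.mean(axis=0)
    trend = lowess_sqrt_sd_trend(mean_log2cpm, np.sqrt(sd))
    fitted = H @ Y
    w = 1.0 / np.maximum(trend(fitted), 1e-6) ** 4  # per-observation weights

    from scipy import stats

    out = []
    for cls in sorted(pd.unique(annotation)):
        ind = (annotation == cls).astype(float)
        n1 = int(ind.sum())
        if n1 < 2 or n - n1 < 2:
            raise ValueError(f"contrast {cls!r} has a side with < 2 units")
        X = np.column_stack([base, ind])
        pcol = X.shape[1] - 1
        beta = np.empty(len(genes))
        s2 = np.empty(len(genes))
        vb = np.empty(len(genes))
        dfr = n - np.linalg.matrix_rank(X)
        for j in range(len(genes)):
            Wj = w[:, j]
            Xw = X * Wj[:, None]
            XtX = X.T @ Xw
            XtXi = np.linalg.pinv(XtX)
            b = XtXi @ (Xw.T @ Y[:, j])
            r = Y[:, j] - X @ b
            beta[j] = b[pcol]
            s2[j] = (Wj * r * r).sum() / dfr
            vb[j] = XtXi[pcol, pcol]
        s2_post, d0, _ = squeeze_var(s2, dfr)
        tstat = beta / np.sqrt(s2_post * vb)
        df_tot = dfr + (d0 if np.isfinite(d0) else 0.0)
        p = 2 * (stats.norm.sf(np.abs(tstat)) if np.isinf(d0) else stats.t.sf(np.abs(tstat), df_tot))
        out.append(pd.DataFrame({
            "annotation": cls, "gene": genes, "logFC": beta, "t": tstat,
            "p_value": p, "fdr": bh_fdr(p),
        }))
    return pd.concat(out, ignore_index=True)
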