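"""Airspace pseudotime and negative-binomial GAM association tests.

Alveolar airspaces are ordered along a remodeling axis by the share of their
nuclear transcripts assigned to the healthy alveolar transcript niche:
descending healthy share gives ascending pseudotime, taken as rank/N in
(0, 1]. Feature counts aggregated per airspace (genes, cell types, niches)
are then modeled with penalized negative-binomial GAMs,

    log mu = s(t) [+ sum_i s(p_i)] + log n + U,

where s() are cubic regression splines with 5 knots at pseudotime quantiles
under a sum-to-zero constraint and a second-difference penalty, log n is a
fixed offset (total transcripts or cells per airspace), U a categorical TMA
batch covariate and p_i optional cell-type composition covariates that absorb
contamination signal. Dispersion is estimated per feature by maximum
likelihood; the smoothing parameter by GCV on a log grid. Association with
pseudotime is a Wald test that all s(t) coefficients are jointly zero, using
the sandwich covariance of the penalized estimator, with BH-FDR across
features.

Significant genes' predicted smooths (2,000 time points, z-scored) are
clustered hierarchically (k=20) to split bimodal from unimodal shapes by an
explicit peak rule, unimodal genes are spectrally clustered (k=4), and the
four clusters are labeled homeostasis / early / intermediate / late
remodeling by their mean peak time (rolling mean, window 100).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from scipy.linalg import null_space

from ._stats import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "SmoothTerm",
    "GamFit",
    "order_airspaces",
    "fit_nb_gam",
    "fit_feature_gams",
    "association_test",
    "predicted_smooths",
    "classify_patterns",
    "celltype_level_gam",
    "rolling_peak_time",
]

STAGE_LABELS = ("homeostasis", "early", "intermediate", "late")


# ---------------------------------------------------------------------------
# pseudotime ordering
# ---------------------------------------------------------------------------

def order_airspaces(
    transcript_labels: pd.DataFrame | None = None,
    healthy_niche: str = "T4",
    shares: pd.Series | None = None,
    niche_col: str = "transcript_niche",
) -> pd.DataFrame:
    """Order airspaces by descending healthy-niche transcript share.

    Either pass ``transcript_labels`` (one row per nuclear transcript with
    ``airspace_id`` and a niche label column) or precomputed ``shares``
    indexed by airspace id. Ties in share break by airspace id. Returns a
    DataFrame with ``airspace_id``, ``healthy_share`` and ``pseudotime`` =
    rank/N in (0, 1] (1 = fully remodeled).
    """
    if shares is None:
        if transcript_labels is None:
            raise ValueError("pass transcript_labels or shares")
        grp = transcript_labels.groupby("airspace_id", sort=True)[niche_col]
        shares = grp.apply(lambda s: float((s == healthy_niche).mean()))
    shares = shares.sort_index()
    order = sorted(shares.index, key=lambda a: (-shares[a], a))
    n = len(order)
    out = pd.DataFrame({
        "airspace_id": order,
        "healthy_share": [shares[a] for a in order],
        "pseudotime": (np.arange(n) + 1) / n,
    })
    return out


# ---------------------------------------------------------------------------
# spline machinery
# ---------------------------------------------------------------------------

@dataclass
class SmoothTerm:
    """A constrained penalized cubic-spline smooth of one covariate."""

    name: str
    knots: np.ndarray        # full (clamped) knot vector
    Z: np.ndarray            # sum-to-zero constraint basis (p_raw x p)
    sl: slice                # coefficient columns in the design matrix
    S: np.ndarray            # constrained penalty block (p x p)

    def basis(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.knots[0], self.knots[-1])
        B = BSpline.design_matrix(x, self.knots, 3, extrapolate=False).toarray()
        return B @ self.Z


def _make_smooth(name: str, x: np.ndarray, n_knots: int = 5) -> tuple[np.ndarray, SmoothTerm]:
    """Constrained cubic-spline basis with ``n_knots`` quantile knots and a
    second-difference penalty; returns (basis columns, term)."""
    x = np.asarray(x, dtype=float)
    q = np.quantile(x, np.linspace(0, 1, n_knots))
    q = np.unique(q)
    if len(q) < 2:
        raise ValueError(f"covariate {name!r} is constant; cannot build a smooth")
    knots = np.r_[[q[0]] * 3, q, [q[-1]] * 3]
    B = BSpline.design_matrix(x, knots, 3, extrapolate=False).toarray()
    # sum-to-zero constraint over the observed covariate values
    C = B.mean(axis=0, keepdims=True)
    Z = null_space(C)
    D = np.diff(np.eye(B.shape[1]), n=2, axis=0)
    S = Z.T @ (D.T @ D) @ Z
    term = SmoothTerm(name=name, knots=knots, Z=Z, sl=slice(0, 0), S=S)
    return B @ Z, term


@dataclass
class GamFit:
    """A fitted penalized negative-binomial GAM for one feature."""

    feature: str
    beta: np.ndarray
    cov: np.ndarray              # sandwich covariance of beta
    smooths: dict[str, SmoothTerm]
    alpha: float                 # NB dispersion (var = mu + alpha mu^2)
    lam: float                   # smoothing parameter
    edf: float
    converged: bool
    offset_mean: float = 0.0
    deviance: float = float("nan")
    wald_stat: float = float("nan")
    wald_df: int = 0
    p_value: float = float("nan")

    def smooth_values(self, name: str, grid: np.ndarray) -> np.ndarray:
        """Centered smooth s(name) evaluated on a covariate grid."""
        term = self.smooths[name]
        return term.basis(grid) @ self.beta[term.sl]

    def predict_rate(self, grid: np.ndarray, smooth: str = "t") -> np.ndarray:
        """exp(intercept + s(t) + mean offset): expected counts along the
        smooth with other covariates at reference levels."""
        return np.exp(self.beta[0] + self.smooth_values(smooth, grid) + self.offset_mean)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    if alpha < 1e-8:
        return float(np.sum(stats.poisson.logpmf(y, mu)))
    r = 1.0 / alpha
    return float(np.sum(stats.nbinom.logpmf(y, r, r / (r + mu))))


def _estimate_alpha(y: np.ndarray, mu: np.ndarray, lo: float = 1e-6, hi: float = 10.0) -> float:
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda la: -_nb_loglik(y, mu, np.exp(la)),
        bounds=(np.log(lo), np.log(hi)), method="bounded",
        options={"xatol": 1e-3},
    )
    return float(np.exp(res.x))


def _pirls(y, X, S_full, offset, alpha, lam, max_iter=50, tol=1e-8):
    """Penalized IRLS for an NB log-link model; returns beta, mu, A=X'WX, edf."""
    n, p = X.shape
    mu = np.maximum(y, 0.5)
    eta = np.log(mu) - offset
    beta = np.zeros(p)
    P = lam * S_full + 1e-9 * np.eye(p)
    dev_old = np.inf
    converged = False
    for _ in range(max_iter):
        w = mu / (1.0 + alpha * mu)
        z = eta + (y - mu) / mu
        Xw = X * w[:, None]
        A = X.T @ Xw
        beta_new = np.linalg.solve(A + P, Xw.T @ z)
        eta = np.clip(X @ beta_new, -30, 30)
        mu = np.exp(eta + offset)
        mu = np.clip(mu, 1e-10, 1e10)
        dev = -2.0 * _nb_loglik(y, mu, alpha)
        if abs(dev - dev_old) < tol * (abs(dev) + 0.1):
            beta = beta_new
            converged = True
            break
        beta = beta_new
        dev_old = dev
    w = mu / (1.0 + alpha * mu)
    Xw = X * w[:, None]
    A = X.T @ Xw
    edf = float(np.trace(np.linalg.solve(A + P, A)))
    return beta, mu, A, P, edf, dev, converged


def fit_nb_gam(
    y: np.ndarray,
    smooth_covs: dict[str, np.ndarray],
    offset: np.ndarray | None = None,
    factor: np.ndarray | None = None,
    n_knots: int = 5,
    lam: float | str = "gcv",
    lam_grid: np.ndarray | None = None,
    feature: str = "feature",
    drop_collinear: bool = True,
) -> GamFit:
    """Fit one penalized negative-binomial GAM.

    ``smooth_covs`` maps smooth names to covariate vectors (the pseudotime
    smooth is conventionally named ``"t"``); ``offset`` is the log exposure
    (default 0); ``factor`` an optional categorical batch covariate (dummy
    coded, first level absorbed). ``lam="gcv"`` selects the shared smoothing
    parameter on a log grid by generalized cross-validation. Composition
    smooths made collinear by degenerate covariates are dropped with a log
    message when ``drop_collinear``.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    offset = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)

    cols = [np.ones((n, 1))]
    smooths: dict[str, SmoothTerm] = {}
    pos = 1
    for name, x in smooth_covs.items():
        x = np.asarray(x, dtype=float)
        try:
            Bc, term = _make_smooth(name, x, n_knots)
        except ValueError:
            if drop_collinear:
                logger.info("%s: smooth %r degenerate; dropped", feature, name)
                continue
            raise
        term.sl = slice(pos, pos + Bc.shape[1])
        smooths[name] = term
        cols.append(Bc)
        pos += Bc.shape[1]
    if factor is not None:
        factor = np.asarray(factor)
        levels = sorted(pd.unique(factor))
        for lv in levels[1:]:
            cols.append((factor == lv).astype(float)[:, None])
            pos += 1
    X = np.hstack(cols)
    p = X.shape[1]

    if drop_collinear and np.linalg.matrix_rank(X) < p and smooths:
        # drop trailing composition smooths until full rank (keep "t")
        for name in [k for k in reversed(list(smooths)) if k != "t"]:
            logger.info("%s: dropping collinear smooth %r", feature, name)
            sl = smooths.pop(name).sl
            keep = np.r_[np.arange(sl.start), np.arange(sl.stop, X.shape[1])]
            X = X[:, keep]
            shift = sl.stop - sl.start
            for t2 in smooths.values():
                if t2.sl.start >= sl.stop:
                    t2.sl = slice(t2.sl.start - shift, t2.sl.stop - shift)
            if np.linalg.matrix_rank(X) == X.shape[1]:
                break
        p = X.shape[1]

    S_full = np.zeros((p, p))
    for term in smooths.values():
        S_full[term.sl, term.sl] = term.S

    # moment start for dispersion, then alternate beta | alpha
    mu0 = np.maximum(y.mean(), 0.5)
    alpha = max(1e-4, float((y.var() - mu0) / mu0**2)) if y.var() > mu0 else 1e-4

    def fit_at(lam_val, alpha_val):
        return _pirls(y, X, S_full, offset, alpha_val, lam_val)

    if lam == "gcv" and smooths:
        grid = lam_grid if lam_grid is not None else np.logspace(-2, 4, 7)
        best, best_gcv = grid[0], np.inf
        for lv in grid:
            _, mu, _, _, edf, dev, _ = fit_at(lv, alpha)
            gcv = n * dev / max(n - edf, 1.0) ** 2
            if gcv < best_gcv:
                best, best_gcv = lv, gcv
        lam_val = float(best)
    else:
        lam_val = 1.0 if lam == "gcv" else float(lam)

    beta = None
    for _ in range(3):
        beta, mu, A, P, edf, dev, conv = fit_at(lam_val, alpha)
        alpha_new = _estimate_alpha(y, mu, hi=max(10.0, 2 * alpha))
        if abs(np.log(alpha_new + 1e-8) - np.log(alpha + 1e-8)) < 1e-3:
            alpha = alpha_new
            break
        alpha = alpha_new
    beta, mu, A, P, edf, dev, conv = fit_at(lam_val, alpha)

    Minv = np.linalg.inv(A + P)
    cov = Minv @ A @ Minv  # sandwich covariance of the penalized estimator
    return GamFit(
        feature=feature, beta=beta, cov=cov, smooths=smooths, alpha=alpha,
        lam=lam_val, edf=edf, converged=conv, offset_mean=float(offset.mean()),
        deviance=dev,
    )


# ---------------------------------------------------------------------------
# per-feature fitting, association testing, pattern classification
# ---------------------------------------------------------------------------

def eligible_features(
    counts: pd.DataFrame, min_count: int = 3, min_airspaces: float = 10
) -> np.ndarray:
    """Features present with > ``min_count`` - 1 counts in enough airspaces.

    ``min_airspaces`` is an absolute airspace count, or a fraction of
    airspaces when < 1 (the niche rule uses 10%).
    """
    thr = min_airspaces if min_airspaces >= 1 else min_airspaces * len(counts)
    n_hit = (counts.to_numpy() >= min_count).sum(axis=0)
    return counts.columns.to_numpy()[n_hit >= thr]


def fit_feature_gams(
    counts: pd.DataFrame,
    trajectory: pd.DataFrame,
    offset: np.ndarray | str = "rowsum",
    tma: np.ndarray | None = None,
    min_count: int = 3,
    min_airspaces: float = 10,
    n_knots: int = 5,
    lam: float | str = "gcv",
) -> dict[str, GamFit]:
    """Fit a pseudotime GAM per eligible feature column.

    ``counts`` is airspace x feature (rows aligned to
    ``trajectory.airspace_id``); ``offset`` is a log-exposure vector, or
    ``"rowsum"`` to use the log of the row totals (total transcripts for
    gene models, total cells for cell-type models). Non-converged fits are
    kept but flagged; :func:`association_test` excludes them.
    """
    counts = counts.loc[trajectory["airspace_id"]]
    t = trajectory["pseudotime"].to_numpy()
    if isinstance(offset, str) and offset == "rowsum":
        off = np.log(np.maximum(counts.to_numpy().sum(axis=1), 1.0))
    else:
        off = np.asarray(offset, dtype=float)
    feats = eligible_features(counts, min_count, min_airspaces)
    logger.info("fitting GAMs for %d/%d eligible features", len(feats), counts.shape[1])
    fits: dict[str, GamFit] = {}
    for f in feats:
        fits[f] = fit_nb_gam(
            counts[f].to_numpy(), {"t": t}, offset=off, factor=tma,
            n_knots=n_knots, lam=lam, feature=str(f),
        )
    return fits


def association_test(fits: dict[str, GamFit], smooth: str = "t") -> pd.DataFrame:
    """Wald test that all coefficients of ``s(smooth)`` are jointly zero.

    Uses the sandwich covariance of the penalized estimator; the statistic is
    the quadratic form b' V^- b with chi-square reference on rank(V) degrees
    of freedom. Non-converged fits are excluded. Adds BH-FDR.
    """
    rows = []
    for name, fit in fits.items():
        if not fit.converged or smooth not in fit.smooths:
            continue
        sl = fit.smooths[smooth].sl
        b = fit.beta[sl]
        V = fit.cov[sl, sl]
        Vinv = np.linalg.pinv(V, rcond=1e-10)
        stat = float(b @ Vinv @ b)
        df = int(np.linalg.matrix_rank(V))
        p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
        fit.wald_stat, fit.wald_df, fit.p_value = stat, df, p
        rows.append({"feature": name, "wald": stat, "df": df, "p_value": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    else:
        out["fdr"] = []
    return out


def predicted_smooths(fits: dict[str, GamFit], n_grid: int = 2000) -> pd.DataFrame:
    """Predicted expected counts along pseudotime (rows = grid, cols = features)."""
    grid = np.linspace(1.0 / n_grid, 1.0, n_grid)
    cols = {name: fit.predict_rate(grid) for name, fit in fits.items() if fit.converged}
    return pd.DataFrame(cols, index=grid)


def rolling_peak_time(profile: np.ndarray, window: int = 100) -> float:
    """Peak position (fractional index in [0, 1]) of a profile's rolling mean."""
    profile = np.asarray(profile, dtype=float)
    w = min(window, len(profile))
    sm = np.convolve(profile, np.ones(w) / w, mode="valid")
    idx = int(np.argmax(sm)) + (w - 1) / 2.0
    return float(idx / max(len(profile) - 1, 1))


def _is_bimodal(z: np.ndarray, peak_height: float = 0.5, trough: float = 0.0) -> bool:
    """Explicit surrogate for by-eye bimodality: at least two local maxima
    above ``peak_height`` (z units) separated by a dip below ``trough``."""
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(z, height=peak_height)
    if len(z) and z[0] > peak_height and (len(z) > 1 and z[0] > z[1]):
        peaks = np.r_[0, peaks]
    if len(z) and z[-1] > peak_height and (len(z) > 1 and z[-1] > z[-2]):
        peaks = np.r_[peaks, len(z) - 1]
    if len(peaks) < 2:
        return False
    for a, b in zip(peaks[:-1], peaks[1:]):
        if z[a:b + 1].min() < trough:
            return True
    return False


def classify_patterns(
    smooths: pd.DataFrame,
    window: int = 100,
    n_hier: int = 20,
    n_stage: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Classify predicted expression smooths into bimodal + four stage classes.

    ``smooths`` is the grid x gene output of :func:`predicted_smooths`.
    Profiles are z-scored per gene, grouped by Ward hierarchical clustering
    (k=20); clusters whose mean profile fails/passes the explicit bimodality
    rule split genes into unimodal/bimodal. Unimodal genes are clustered
    spectrally (k=4) and the clusters labeled homeostasis/early/intermediate/
    late by increasing mean rolling-peak time. Returns gene, pattern label,
    and peak_time. Fewer than ``n_stage`` unimodal genes: stage clustering is
    skipped and unimodal genes are labeled by peak-time bins directly.
    """
    genes = smooths.columns.to_numpy()
    Z = smooths.to_numpy().T  # gene x grid
    mu = Z.mean(axis=1, keepdims=True)
    sd = Z.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Zs = (Z - mu) / sd
    peak = np.array([rolling_peak_time(z, window) for z in Zs])

    from scipy.cluster.hierarchy import fcluster, linkage

    k_h = min(n_hier, len(genes))
    if len(genes) > 1:
        hl = fcluster(linkage(Zs, method="ward"), t=k_h, criterion="maxclust")
    else:
        hl = np.ones(1, dtype=int)
    bimodal = np.zeros(len(genes), dtype=bool)
    for c in np.unique(hl):
        m = hl == c
        if _is_bimodal(Zs[m].mean(axis=0)):
            bimodal[m] = True

    labels = np.array(["bimodal"] * len(genes), dtype=object)
    uni = np.flatnonzero(~bimodal)
    if len(uni) >= n_stage:
        from sklearn.cluster import SpectralClustering

        sc = SpectralClustering(
            n_clusters=n_stage, affinity="nearest_neighbors",
            n_neighbors=min(10, len(uni) - 1), random_state=seed,
            assign_labels="discretize",
        )
        cl = sc.fit_predict(Zs[uni])
        order = np.argsort([peak[uni][cl == c].mean() for c in range(n_stage)])
        stage_of = {c: STAGE_LABELS[r] for r, c in enumerate(order)}
        labels[uni] = [stage_of[c] for c in cl]
    elif len(uni):
        logger.warning("only %d unimodal genes; stage clustering skipped", len(uni))
        bins = np.clip((peak[uni] * n_stage).astype(int), 0, n_stage - 1)
        labels[uni] = [STAGE_LABELS[b] for b in bins]
    return pd.DataFrame({"gene": genes, "pattern": labels, "peak_time": peak})


def celltype_level_gam(
    counts_by_celltype: dict[str, pd.DataFrame],
    trajectory: pd.DataFrame,
    composition: pd.DataFrame,
    offset: np.ndarray,
    tma: np.ndarray | None = None,
    celltype_cells: pd.DataFrame | None = None,
    significant_genes: set[str] | None = None,
    min_cells: int = 3,
    min_celltype_airspaces: int = 80,
    min_composition_airspaces: int = 300,
    max_composition: int = 15,
    gene_min_copies: int = 3,
    gene_min_fraction: float = 0.5,
    n_knots: int = 5,
    lam: float | str = "gcv",
) -> tuple[dict[tuple[str, str], GamFit], pd.DataFrame]:
    """Composition-adjusted per-(cell type, gene) pseudotime GAMs.

    For each eligible cell type, every eligible gene is fit with
    log mu = s(t) + sum_i s(p_i) + offset + TMA and tested for the s(t) term.

    Eligibility: cell types with > ``min_cells`` - 1 cells in at least
    ``min_celltype_airspaces`` airspaces (needs ``celltype_cells``, an
    airspace x cell-type cell-count table; otherwise all supplied types are
    tested); composition covariates are the <= ``max_composition`` types with
    > ``min_cells`` - 1 cells in more than ``min_composition_airspaces``
    airspaces; genes restricted to ``significant_genes`` (when given) and to
    genes with >= ``gene_min_copies`` copies in ``gene_min_fraction`` of the
    airspaces. Returns the fits keyed by (cell type, gene) and a tidy result
    table with BH-FDR over all tests.
    """
    aid = trajectory["airspace_id"]
    t = trajectory["pseudotime"].to_numpy()
    comp = composition.loc[aid]

    if celltype_cells is not None:
        cc = celltype_cells.loc[aid]
        n_hit = (cc >= min_cells).sum(axis=0)
        tested_types = [c for c in counts_by_celltype if c in cc and n_hit[c] >= min_celltype_airspaces]
        comp_prev = (cc >= min_cells).sum(axis=0)
        comp_types = [c for c in cc.columns if comp_prev[c] > min_composition_airspaces]
        comp_types = sorted(comp_types, key=lambda c: -comp_prev[c])[:max_composition]
    else:
        tested_types = list(counts_by_celltype)
        comp_types = [c for c in comp.columns][:max_composition]

    smooth_covs_base = {f"p_{c}": comp[c].to_numpy() for c in comp_types if c in comp}

    fits: dict[tuple[str, str], GamFit] = {}
    rows = []
    for ct in tested_types:
        sub = counts_by_celltype[ct].loc[aid]
        genes = [g for g in sub.columns
                 if (sub[g].to_numpy() >= gene_min_copies).mean() >= gene_min_fraction]
        if significant_genes is not None:
            genes = [g for g in genes if g in significant_genes]
        for g in genes:
            covs = {"t": t}
            covs.update(smooth_covs_base)
            fit = fit_nb_gam(
                sub[g].to_numpy(), covs, offset=offset, factor=tma,
                n_knots=n_knots, lam=lam, feature=f"{ct}:{g}",
            )
            fits[(ct, g)] = fit
            if fit.converged and "t" in fit.smooths:
                sl = fit.smooths["t"].sl
                b = fit.beta[sl]
                V = fit.cov[sl, sl]
                stat = float(b @ np.linalg.pinv(V, rcond=1e-10) @ b)
                df = int(np.linalg.matrix_rank(V))
                p = float(stats.chi2.sf(stat, df))
            else:
                stat, df, p = np.nan, 0, np.nan
            rows.append({"cell_type": ct, "gene": g, "wald": stat, "df": df, "p_value": p})
    res = pd.DataFrame(rows)
    if len(res):
        res["fdr"] = bh_fdr(res["p_value"].to_numpy())
    return fits, res
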