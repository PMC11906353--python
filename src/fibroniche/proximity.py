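"""Pairwise cell-type proximity statistics.

For every ordered pair of cell types (anchor A, target B), each cell is
binarized as proximal (it has at least one type-B neighbor within a fixed
radius, 60 µm by default) or nonproximal, and a logistic regression with the
is-type-A indicator as covariate estimates how much more likely A cells are
to be proximal to B than other cells are. With a single binary covariate the
maximum-likelihood log odds ratio has the closed form log(n11*n00/(n10*n01))
of the 2x2 contingency table, which is what is computed here, together with
the Wald 5-95% confidence interval, a two-sided p-value and BH-FDR across
pairs within each stratum. The analysis runs over all cells and, optionally,
within each niche separately; A-near-B and B-near-A are distinct results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from ._stats import bh_fdr

__all__ = ["find_neighbors", "proximity_logit", "ProximityResult"]


@dataclass
class ProximityResult:
    """One anchor/target pair in one stratum."""

    anchor_type: str
    neighbor_type: str
    stratum: str
    log_odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    fdr: float
    n_anchor: int
    degenerate: bool


def find_neighbors(cells: pd.DataFrame, radius: float = 60.0) -> pd.DataFrame:
    """All within-radius neighbor pairs per sample, with distance and angle.

    Returns one row per ordered pair (anchor, neighbor) with ``distance`` <=
    ``radius`` and the ``angle`` (radians, anchor -> neighbor); the relation
    is symmetric, so both directions appear. Self pairs are excluded.
    """
    parts = []
    for _, sub in cells.groupby("sample_id", sort=True):
        xy = sub[["x", "y"]].to_numpy(dtype=float)
        ids = sub["cell_id"].to_numpy()
        pairs = cKDTree(xy).query_pairs(r=radius, output_type="ndarray")
        if len(pairs) == 0:
            continue
        i, j = pairs[:, 0], pairs[:, 1]
        dxy = xy[j] - xy[i]
        dist = np.hypot(dxy[:, 0], dxy[:, 1])
        ang = np.arctan2(dxy[:, 1], dxy[:, 0])
        parts.append(pd.DataFrame({
            "anchor": np.r_[ids[i], ids[j]],
            "neighbor": np.r_[ids[j], ids[i]],
            "distance": np.r_[dist, dist],
            "angle": np.r_[ang, np.arctan2(-dxy[:, 1], -dxy[:, 0])],
        }))
    if not parts:
        return pd.DataFrame(columns=["anchor", "neighbor", "distance", "angle"])
    return pd.concat(parts, ignore_index=True)


def _pair_table(y: np.ndarray, is_anchor_type: np.ndarray) -> tuple[float, float, bool]:
    """Closed-form logistic log-OR and its SE from the 2x2 table; degenerate
    tables get a Haldane-Anscombe 0.5 correction and a flag."""
    n11 = float(np.sum(y & is_anchor_type))        # anchor type, proximal
    n10 = float(np.sum(~y & is_anchor_type))       # anchor type, nonproximal
    n01 = float(np.sum(y & ~is_anchor_type))
    n00 = float(np.sum(~y & ~is_anchor_type))
    degenerate = min(n11, n10, n01, n00) == 0
    if degenerate:
        n11, n10, n01, n00 = n11 + 0.5, n10 + 0.5, n01 + 0.5, n00 + 0.5
    log_or = np.log(n11 * n00 / (n10 * n01))
    se = np.sqrt(1.0 / n11 + 1.0 / n10 + 1.0 / n01 + 1.0 / n00)
    return log_or, se, degenerate


def proximity_logit(
    neighbors: pd.DataFrame,
    cells: pd.DataFrame,
    stratum: str | None = None,
    ci_quantiles: tuple[float, float] = (0.05, 0.95),
) -> pd.DataFrame:
    """Pairwise proximity log odds ratios with CIs and within-stratum FDR.

    ``neighbors`` is the output of :func:`find_neighbors`. ``stratum`` names
    an optional cell column (e.g. a niche label); when given, the analysis is
    repeated within each stratum value (both anchor and neighbor restricted
    to the stratum) in addition to the pooled ``"all"`` stratum. Pairs whose
    anchor type has fewer than two cells, or whose 2x2 table has an empty
    cell, are flagged ``degenerate`` (estimates clamped via a 0.5 continuity
    correction; no-estimate cases carry NaN).
    """
    if "cell_type" not in cells:
        raise ValueError("cells must carry a cell_type column")
    z = stats.norm.ppf(ci_quantiles[1])
    strata: list[tuple[str, pd.DataFrame]] = [("all", cells)]
    if stratum is not None:
        for val, sub in cells.groupby(stratum, sort=True):
            strata.append((str(val), sub))

    rows: list[ProximityResult] = []
    type_of = cells.set_index("cell_id")["cell_type"]
    nb = neighbors.copy()
    nb["neighbor_type"] = type_of.reindex(nb["neighbor"]).to_numpy()

    for name, sub in strata:
        ids = sub["cell_id"].to_numpy()
        id_set = pd.Index(ids)
        nb_s = nb[nb["anchor"].isin(id_set) & nb["neighbor"].isin(id_set)]
        types = np.asarray(sorted(sub["cell_type"].unique()))
        if len(types) < 2:
            warnings.warn(f"stratum {name!r} has <2 cell types; skipped", stacklevel=2)
            continue
        # proximal indicator: cell x target-type boolean
        has = pd.crosstab(nb_s["anchor"], nb_s["neighbor_type"]) > 0
        has = has.reindex(index=ids, columns=types, fill_value=False)
        ct = sub["cell_type"].to_numpy()

        stratum_rows: list[ProximityResult] = []
        for a in types:
            is_a = ct == a
            n_anchor = int(is_a.sum())
            for b in types:
                y = has[b].to_numpy()
                if n_anchor < 2 or n_anchor == len(ct):
                    stratum_rows.append(ProximityResult(a, b, name, np.nan, np.nan, np.nan,
                                                        np.nan, np.nan, n_anchor, True))
                    continue
                log_or, se, degen = _pair_table(y, is_a)
                wald = log_or / se
                p = 2.0 * stats.norm.sf(abs(wald))
                stratum_rows.append(ProximityResult(
                    a, b, name, log_or, log_or - z * se, log_or + z * se, p, np.nan,
                    n_anchor, degen,
                ))
        pvals = np.array([r.p_value for r in stratum_rows])
        fdr = bh_fdr(pvals)
        for r, q in zip(stratum_rows, fdr):
            r.fdr = float(q) if np.isfinite(q) else np.nan
        rows.extend(stratum_rows)

    return pd.DataFrame([vars(r) for r in rows])
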