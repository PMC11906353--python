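"""Lumen segmentation and alveolar airspace identification.

Tissue lumens (alveoli, airway and vessel interiors) are negative space:
regions without transcripts enclosed by tissue. Transcript positions —
excluding transcripts of immune cells, which accumulate inside airspaces —
are binarized onto a raster; dilation/erosion/closing turn the point pattern
into a solid tissue mask; the enclosed background components are labeled as
lumens; and the concave outer boundary of the tissue is traced with an alpha
shape (Delaunay triangles filtered by circumradius). Cell nuclei within a
wall-thickness cutoff of a lumen are assigned to it via a nearest-label
lookup, and per-lumen metrics feed compositional filters that isolate lumens
of likely alveolar origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import Polygon
from shapely.ops import unary_union

logger = logging.getLogger(__name__)

__all__ = [
    "MorphologyConfig",
    "TissueMask",
    "alpha_shape",
    "rasterize_transcripts",
    "segment_lumens",
    "assign_cells_to_lumens",
    "compute_lumen_metrics",
    "filter_alveolar",
]

#: cell niches allowed as a lumen's "maximum cell niche" for alveolar origin
ALVEOLAR_MAX_NICHES = frozenset({"C2", "C5", "C8", "C3", "C11"})
#: endothelial-niche proportion ceilings (vessel exclusion)
ENDOTHELIAL_LIMITS = {"C10": 0.3, "C12": 0.3}
#: airway-niche proportion ceiling
AIRWAY_LIMITS = {"C1": 0.2}


@dataclass(frozen=True)
class MorphologyConfig:
    """Structuring-element radii (pixels) for the tissue-mask morphology."""

    dilation_px: int = 1
    erosion_px: int = 1
    closing_px: int = 4

    def __post_init__(self) -> None:
        if min(self.dilation_px, self.erosion_px, self.closing_px) < 0:
            raise ValueError("structuring radii must be >= 0")


@dataclass
class TissueMask:
    """Solid tissue raster plus its alpha-shape outer boundary polygon."""

    mask: np.ndarray            # bool (rows, cols); True = tissue or enclosed space
    boundary: Polygon
    resolution: float           # µm per pixel


def _disk(radius: int) -> np.ndarray:
    if radius == 0:
        return np.ones((1, 1), dtype=bool)
    y, x = np.ogrid[-radius: radius + 1, -radius: radius + 1]
    return x * x + y * y <= radius * radius


def alpha_shape(points: np.ndarray, alpha: float) -> Polygon:
    """Alpha shape of a 2-D point cloud.

    Keeps Delaunay triangles whose circumradius is below ``1/alpha`` and
    returns the union (largest polygon if the union is disconnected).
    Requires at least 3 non-collinear points.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("alpha shape needs >= 3 points")
    tri = Delaunay(pts)
    a, b, c = (pts[tri.simplices[:, i]] for i in range(3))
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    s = (la + lb + lc) / 2.0
    area = np.sqrt(np.maximum(s * (s - la) * (s - lb) * (s - lc), 1e-30))
    circum_r = la * lb * lc / (4.0 * area)
    keep = circum_r < 1.0 / alpha
    if not keep.any():
        raise ValueError("alpha too large: no triangle passes the circumradius filter")
    polys = [Polygon(t) for t in pts[tri.simplices[keep]]]
    merged = unary_union(polys)
    if merged.geom_type == "MultiPolygon":
        merged = max(merged.geoms, key=lambda g: g.area)
    return Polygon(merged.exterior)


def rasterize_transcripts(
    t: pd.DataFrame,
    cells: pd.DataFrame | None = None,
    resolution: float = 5.0,
    exclude_lineage: str = "immune",
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Binarize transcript locations to a 2-D raster.

    A pixel is set when at least one eligible transcript falls in it
    (floor division of µm coordinates by ``resolution``). Transcripts whose
    ``nucleus_id`` belongs to a cell of ``exclude_lineage`` (requires a
    ``lineage`` column in ``cells``) are excluded, so intraluminal immune
    cells do not close off airspaces. The raster origin is (0, 0).
    """
    use = np.ones(len(t), dtype=bool)
    if cells is not None and "lineage" in cells:
        excl = set(cells.loc[cells["lineage"] == exclude_lineage, "cell_id"])
        if excl:
            use &= ~t["nucleus_id"].isin(excl).to_numpy()
    xy = t.loc[use, ["x_location", "y_location"]].to_numpy(dtype=float)
    if shape is None:
        if len(xy) == 0:
            return np.zeros((1, 1), dtype=bool)
        shape = (int(np.floor(xy[:, 1].max() / resolution)) + 1,
                 int(np.floor(xy[:, 0].max() / resolution)) + 1)
    raster = np.zeros(shape, dtype=bool)
    if len(xy):
        cols = np.floor(xy[:, 0] / resolution).astype(int)
        rows = np.floor(xy[:, 1] / resolution).astype(int)
        ok = (rows >= 0) & (rows < shape[0]) & (cols >= 0) & (cols < shape[1])
        raster[rows[ok], cols[ok]] = True
    return raster


def segment_lumens(
    raster: np.ndarray,
    resolution: float = 5.0,
    morph: MorphologyConfig | None = None,
    alpha: float | None = None,
) -> tuple[TissueMask, np.ndarray]:
    """Segment enclosed negative space into labeled lumens.

    The transcript raster is dilated, eroded and closed into a solid tissue
    mask; background components fully enclosed by tissue become lumens
    (labels 1..L). Components connected to the exterior of the tissue are
    not holes and receive no label. The outer boundary polygon (µm) comes
    from an alpha shape over occupied pixel centers; ``alpha`` defaults to
    1 / (4 pixels), loose enough to follow a concave tissue edge.
    """
    from skimage import measure

    morph = morph or MorphologyConfig()
    if int(raster.sum()) < 3:
        raise ValueError("degenerate tissue: fewer than 3 occupied pixels")
    m = raster
    if morph.dilation_px:
        m = ndi.binary_dilation(m, structure=_disk(morph.dilation_px))
    if morph.erosion_px:
        m = ndi.binary_erosion(m, structure=_disk(morph.erosion_px))
    if morph.closing_px:
        m = ndi.binary_closing(m, structure=_disk(morph.closing_px))

    filled = ndi.binary_fill_holes(m)
    negative = filled & ~m
    labeled = measure.label(negative, connectivity=1)
    n = int(labeled.max())
    logger.info("segmented %d lumens", n)

    rows, cols = np.nonzero(m)
    pix_um = np.column_stack([(cols + 0.5) * resolution, (rows + 0.5) * resolution])
    a = alpha if alpha is not None else 1.0 / (4.0 * resolution)
    boundary = alpha_shape(pix_um, a)
    return TissueMask(mask=filled, boundary=boundary, resolution=resolution), labeled


def assign_cells_to_lumens(
    cells: pd.DataFrame,
    labeled: np.ndarray,
    resolution: float = 5.0,
    wall_cutoff: float = 10.0,
) -> pd.DataFrame:
    """Assign each cell to the nearest lumen within ``wall_cutoff`` µm.

    Cells inside a lumen take its label; cells whose centroid is farther
    than the cutoff (normal alveolar wall thickness) from every lumen pixel
    get identifier 0. Returns ``cell_id`` and ``lumen_id``.
    """
    dist, (ri, ci) = ndi.distance_transform_edt(labeled == 0, return_indices=True)
    xy = cells[["x", "y"]].to_numpy(dtype=float)
    rows = np.clip(np.floor(xy[:, 1] / resolution).astype(int), 0, labeled.shape[0] - 1)
    cols = np.clip(np.floor(xy[:, 0] / resolution).astype(int), 0, labeled.shape[1] - 1)
    d_um = dist[rows, cols] * resolution
    lum = labeled[ri[rows, cols], ci[rows, cols]]
    lum = np.where(d_um <= wall_cutoff, lum, 0)
    if not labeled.any():
        lum = np.zeros(len(cells), dtype=int)
    return pd.DataFrame({"cell_id": cells["cell_id"].to_numpy(), "lumen_id": lum})


def _max_pairwise_distance(xy: np.ndarray) -> float:
    """Diameter of a point set (via convex hull when large)."""
    if len(xy) < 2:
        return 0.0
    pts = xy
    if len(xy) > 50:
        from scipy.spatial import ConvexHull, QhullError

        try:
            pts = xy[ConvexHull(xy).vertices]
        except QhullError:
            pass
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    return float(d.max())


def compute_lumen_metrics(
    assignment: pd.DataFrame,
    cells: pd.DataFrame,
) -> pd.DataFrame:
    """Per-lumen QC metrics and cell-niche composition.

    ``assignment`` maps ``cell_id`` to ``lumen_id`` (0 = none);``cells``
    must carry ``x``, ``y``, ``lineage`` and ``cell_niche``. Returns one row
    per lumen with member count, epithelial fraction, the maximum pairwise
    nucleus distance (µm), ``prop_<niche>`` columns and the tied set of
    maximum niches.
    """
    df = assignment.merge(cells, on="cell_id", how="left")
    df = df[df["lumen_id"] > 0]
    niches = np.asarray(sorted(cells["cell_niche"].dropna().unique()))
    rows = []
    for lid, sub in df.groupby("lumen_id", sort=True):
        props = sub["cell_niche"].value_counts(normalize=True)
        props = props.reindex(niches).fillna(0.0)
        top = props.max()
        max_niches = tuple(sorted(props.index[props == top])) if len(sub) else ()
        row = {
            "lumen_id": int(lid),
            "n_cells": len(sub),
            "epithelial_fraction": float((sub["lineage"] == "epithelial").mean()),
            "max_pairwise_nucleus_distance": _max_pairwise_distance(sub[["x", "y"]].to_numpy(float)),
            "max_niches": max_niches,
        }
        row.update({f"prop_{n}": float(props[n]) for n in niches})
        rows.append(row)
    return pd.DataFrame(rows)


def filter_alveolar(
    metrics: pd.DataFrame,
    min_cells: int = 25,
    max_cells: int = 500,
    min_epithelial_fraction: float = 0.05,
    min_max_pairwise: float = 110.0,
    endothelial_limits: dict[str, float] = ENDOTHELIAL_LIMITS,
    airway_limits: dict[str, float] = AIRWAY_LIMITS,
    allowed_max_niches: frozenset[str] = ALVEOLAR_MAX_NICHES,
    return_log: bool = False,
):
    """Apply the five alveolar filters conjunctively.

    Kept lumens have 25-500 cells (inclusive), >= 5% epithelial cells, a
    maximum pairwise nucleus distance >= 110 µm, endothelial-niche
    proportions below the C10/C12 ceilings with the airway C1 ceiling, and a
    maximum-niche set intersecting the allowed alveolar niches (ties count
    if any tied niche is allowed). ``return_log=True`` adds per-lumen
    pass/fail reasons.
    """
    m = metrics
    ok_size = (m["n_cells"] >= min_cells) & (m["n_cells"] <= max_cells)
    ok_epi = m["epithelial_fraction"] >= min_epithelial_fraction
    ok_span = m["max_pairwise_nucleus_distance"] >= min_max_pairwise

    def _below(limits: dict[str, float]) -> pd.Series:
        ok = pd.Series(True, index=m.index)
        for niche, lim in limits.items():
            col = f"prop_{niche}"
            if col in m:
                ok &= m[col] < lim
        return ok

    ok_endo = _below(endothelial_limits)
    ok_air = _below(airway_limits)
    ok_max = m["max_niches"].apply(lambda s: bool(set(s) & allowed_max_niches))
    keep = ok_size & ok_epi & ok_span & ok_endo & ok_air & ok_max
    log = pd.DataFrame({
        "lumen_id": m["lumen_id"],
        "fail_size": ~ok_size,
        "fail_epithelial": ~ok_epi,
        "fail_span": ~ok_span,
        "fail_endothelial": ~ok_endo,
        "fail_airway": ~ok_air,
        "fail_max_niche": ~ok_max,
        "retained": keep,
    })
    out = m.loc[keep].reset_index(drop=True)
    return (out, log) if return_log else out
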