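"""Synthetic Xenium-like tissue with planted ground truth.

The generator emulates the structure of an imaging-based spatial
transcriptomics run on a lung tissue core: per-transcript rows with µm
coordinates, gene labels, decoding quality values (QV), optional nucleus
assignment and probe class; per-cell centroids with nucleus areas; ring-shaped
lumens (alveoli/airways/vessels) whose walls are lined by epithelial cells;
spatially contiguous niche regions with region-specific gene vocabularies; and
"contamination" — transcripts whose gene identity is drawn from an adjacent
cell's expression profile, as happens on the platform when a molecule is
assigned to the wrong nearby cell.

Every generator returns the planted truth alongside the data so downstream
stages (QC, niche discovery, proximity statistics, lumen segmentation,
pseudotime GAMs) can be scored against a known answer.

All randomness flows through a single :class:`numpy.random.Generator` seeded
from the config, so outputs are byte-identical for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "PackingError",
    "PATTERN_CLASSES",
    "generate_tissue",
    "generate_airspace_counts",
    "generate_proximity_cells",
    "write_transcripts",
    "write_truth",
]

#: Expression-pattern classes along the severity axis, in peak-time order.
PATTERN_CLASSES = ("flat", "homeostatic", "early", "intermediate", "late")

#: Peak location (on the severity axis in [0, 1]) of each non-flat pattern.
PATTERN_PEAKS = {"homeostatic": 0.08, "early": 0.35, "intermediate": 0.62, "late": 0.90}

PROBE_CLASSES = (
    "gene",
    "blank",
    "negative_control_probe",
    "negative_control_codeword",
    "unassigned_codeword",
)


class PackingError(RuntimeError):
    """Raised when the requested lumens cannot be packed into the tissue."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic tissue.

    Lengths are µm. Defaults give a small but fully structured tissue core:
    a handful of non-overlapping round lumens whose walls are lined with
    epithelial cells, immune cells sprinkled everywhere, interstitial cells
    between lumens, and ``n_niche_regions`` contiguous (Voronoi) regions each
    emitting its own gene vocabulary on top of cell-type markers.
    """

    tissue_width: float = 700.0
    tissue_height: float = 700.0
    n_lumens: int = 5
    lumen_radius_range: tuple[float, float] = (40.0, 70.0)
    n_cell_types: int = 4
    markers_per_type: int = 4
    n_genes: int = 60
    transcripts_per_cell_mean: float = 80.0
    contamination_rate: float = 0.05
    blank_probe_fraction: float = 0.03
    qv_low_fraction: float = 0.15
    n_niche_regions: int = 4
    seed: int = 0

    # Secondary knobs (rarely changed).
    niche_vocab_per_region: int = 5  # genes private to each niche region
    niche_signal: float = 0.5        # share of a cell's transcripts drawn from its region vocabulary
    n_free_cells: int = 2000         # interstitial (non-wall, non-immune) cells; ~15 µm spacing
    immune_fraction: float = 0.15    # immune cells as a fraction of all placed cells
    cell_radius: float = 7.0         # transcript spread around the nucleus centroid
    nucleus_radius: float = 3.5
    nuclear_fraction: float = 0.6    # transcripts landing inside the nucleus
    wall_cell_spacing: float = 12.0  # µm between adjacent wall cells on a lumen rim
    sample_id: str = "synth_s1"

    def __post_init__(self) -> None:
        counts = {
            "n_lumens": self.n_lumens,
            "n_cell_types": self.n_cell_types,
            "markers_per_type": self.markers_per_type,
            "n_genes": self.n_genes,
            "n_niche_regions": self.n_niche_regions,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        for name in ("contamination_rate", "blank_probe_fraction", "qv_low_fraction",
                     "niche_signal", "nuclear_fraction", "immune_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.lumen_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError(f"invalid lumen_radius_range {self.lumen_radius_range}")
        need = self.n_cell_types * self.markers_per_type + self.n_niche_regions * self.niche_vocab_per_region
        if self.n_genes < need:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {self.n_cell_types}x{self.markers_per_type} "
                f"markers plus {self.n_niche_regions}x{self.niche_vocab_per_region} niche genes ({need})"
            )


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a synthetic dataset.

    Only the fields relevant to the generator that produced it are populated.
    """

    niche_label_transcript: np.ndarray | None = None  # per-transcript region id
    niche_label_cell: np.ndarray | None = None        # per-cell region id
    niche_seeds: np.ndarray | None = None             # region seed points (r, 2)
    lumen_centers: np.ndarray | None = None           # (n_lumens, 2) µm
    lumen_radii: np.ndarray | None = None
    lumen_membership: dict[str, int] = field(default_factory=dict)  # cell id -> lumen id (1-based)
    cell_type_truth: dict[str, str] = field(default_factory=dict)
    lineage_truth: dict[str, str] = field(default_factory=dict)
    trajectory_truth: np.ndarray | None = None        # per-airspace severity in [0, 1]
    tma: np.ndarray | None = None                     # per-airspace batch labels
    de_gene_truth: dict[str, str] = field(default_factory=dict)  # gene -> pattern class
    attraction: float | None = None                   # planted proximity odds multiplier
    attracted_pair: tuple[str, str] | None = None

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), default=default)


# ---------------------------------------------------------------------------
# gene panel and expression profiles
# ---------------------------------------------------------------------------

def _gene_panel(cfg: SyntheticConfig) -> tuple[list[str], dict[int, np.ndarray], dict[int, np.ndarray]]:
    """Build the panel and per-type / per-region emission profiles.

    Panel layout: ``MK{t}_{j}`` markers for each cell type, ``NV{r}_{j}``
    vocabulary genes private to each niche region, ``BG{j}`` shared background.
    Returns (genes, type_profiles, region_profiles) where profiles are
    probability vectors over the panel.
    """
    genes: list[str] = []
    marker_idx: dict[int, list[int]] = {}
    for t in range(cfg.n_cell_types):
        marker_idx[t] = []
        for j in range(cfg.markers_per_type):
            marker_idx[t].append(len(genes))
            genes.append(f"MK{t}_{j}")
    region_idx: dict[int, list[int]] = {}
    for r in range(cfg.n_niche_regions):
        region_idx[r] = []
        for j in range(cfg.niche_vocab_per_region):
            region_idx[r].append(len(genes))
            genes.append(f"NV{r}_{j}")
    n_bg = cfg.n_genes - len(genes)
    bg_idx = list(range(len(genes), len(genes) + n_bg))
    genes.extend(f"BG{j}" for j in range(n_bg))

    G = len(genes)
    type_profiles: dict[int, np.ndarray] = {}
    for t in range(cfg.n_cell_types):
        p = np.zeros(G)
        p[marker_idx[t]] = 0.8 / len(marker_idx[t])
        if bg_idx:
            p[bg_idx] = 0.2 / len(bg_idx)
        else:  # no background genes: renormalize markers
            p /= p.sum()
        type_profiles[t] = p / p.sum()
    region_profiles: dict[int, np.ndarray] = {}
    for r in range(cfg.n_niche_regions):
        p = np.zeros(G)
        p[region_idx[r]] = 1.0 / len(region_idx[r])
        region_profiles[r] = p
    return genes, type_profiles, region_profiles


def _lineage_of(t: int, n_types: int) -> str:
    """Type 0 is epithelial (lumen walls), the last type immune, the rest
    alternate mesenchymal/endothelial."""
    if t == 0:
        return "epithelial"
    if t == n_types - 1 and n_types > 1:
        return "immune"
    return "mesenchymal" if t % 2 == 1 else "endothelial"


def _pack_lumens(cfg: SyntheticConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Sample non-overlapping lumen circles by rejection; raise PackingError
    when the tissue cannot hold them."""
    lo, hi = cfg.lumen_radius_range
    margin = hi + 2 * cfg.cell_radius
    if cfg.tissue_width <= 2 * margin or cfg.tissue_height <= 2 * margin:
        raise PackingError(
            f"tissue {cfg.tissue_width}x{cfg.tissue_height} µm cannot hold lumens of radius up to {hi} µm"
        )
    centers: list[np.ndarray] = []
    radii: list[float] = []
    gap = 3 * cfg.cell_radius  # room for two walls between adjacent lumens
    max_tries = 2000 * cfg.n_lumens
    tries = 0
    while len(centers) < cfg.n_lumens:
        if tries >= max_tries:
            raise PackingError(
                f"could not pack {cfg.n_lumens} lumens (radii {lo}-{hi} µm) into "
                f"{cfg.tissue_width}x{cfg.tissue_height} µm after {max_tries} attempts"
            )
        tries += 1
        r = rng.uniform(lo, hi)
        c = rng.uniform([margin, margin], [cfg.tissue_width - margin, cfg.tissue_height - margin])
        ok = all(np.hypot(*(c - c2)) >= r + r2 + gap for c2, r2 in zip(centers, radii))
        if ok:
            centers.append(c)
            radii.append(r)
    return np.asarray(centers), np.asarray(radii)


def generate_tissue(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate a synthetic tissue core.

    Returns
    -------
    transcripts : DataFrame
        Columns ``x_location, y_location, feature_name, qv, nucleus_id,
        probe_class, sample_id``. ``nucleus_id`` is pandas' nullable string;
        extranuclear and most control transcripts carry ``<NA>``.
    cells : DataFrame
        Columns ``cell_id, x, y, nucleus_area, sample_id, disease_group,
        percent_pathology, tma``.
    truth : SyntheticTruth
        Planted niche regions, lumen geometry/membership, and cell types.

    Raises
    ------
    PackingError
        If the configured lumens cannot be placed without overlap.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes, type_profiles, region_profiles = _gene_panel(cfg)
    centers, radii = _pack_lumens(cfg, rng)

    # --- niche regions: Voronoi cells of random seed points (contiguous) ---
    niche_seeds = rng.uniform(
        [0.0, 0.0], [cfg.tissue_width, cfg.tissue_height], size=(cfg.n_niche_regions, 2)
    )
    seed_tree = cKDTree(niche_seeds)

    # --- place cells ------------------------------------------------------
    xy: list[np.ndarray] = []
    types: list[int] = []
    lumen_of: list[int] = []  # 1-based lumen id, 0 = none

    epi = 0
    immune = cfg.n_cell_types - 1
    interstitial_types = [t for t in range(cfg.n_cell_types) if t not in (epi, immune)] or [epi]

    for li, (c, r) in enumerate(zip(centers, radii), start=1):
        n_wall = max(8, int(round(2 * np.pi * r / cfg.wall_cell_spacing)))
        theta = rng.uniform(0, 2 * np.pi, n_wall)
        rad = r + rng.uniform(0.5, 2.5, n_wall) * cfg.cell_radius
        pts = c + np.c_[rad * np.cos(theta), rad * np.sin(theta)]
        for p in pts:
            xy.append(p)
            types.append(epi)
            lumen_of.append(li)

    def _outside_lumens(p: np.ndarray) -> bool:
        return bool(np.all(np.hypot(*(centers - p).T) > radii + cfg.cell_radius))

    n_free = cfg.n_free_cells
    placed = 0
    while placed < n_free:
        p = rng.uniform([0, 0], [cfg.tissue_width, cfg.tissue_height])
        if _outside_lumens(p):
            xy.append(p)
            types.append(interstitial_types[placed % len(interstitial_types)])
            lumen_of.append(0)
            placed += 1

    n_structural = len(xy)
    n_immune = int(round(cfg.immune_fraction / max(1e-9, 1 - cfg.immune_fraction) * n_structural))
    if cfg.n_cell_types > 1:
        for _ in range(n_immune):
            p = rng.uniform([0, 0], [cfg.tissue_width, cfg.tissue_height])
            xy.append(p)
            types.append(immune)
            # immune cells inside a lumen belong to it (macrophage accumulation)
            d = np.hypot(*(centers - p).T)
            inside = np.flatnonzero(d < radii)
            lumen_of.append(int(inside[0]) + 1 if inside.size else 0)

    xy_arr = np.asarray(xy)
    types_arr = np.asarray(types)
    n_cells = len(xy_arr)
    cell_ids = np.array([f"c{i:05d}" for i in range(n_cells)])
    cell_region = seed_tree.query(xy_arr)[1]

    nucleus_area = np.pi * cfg.nucleus_radius**2 * rng.lognormal(0.0, 0.25, n_cells)

    cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "x": xy_arr[:, 0],
            "y": xy_arr[:, 1],
            "nucleus_area": nucleus_area,
            "sample_id": cfg.sample_id,
            "disease_group": "unaffected",
            "percent_pathology": 0.0,
            "tma": "TMA1",
        }
    )

    # --- transcripts ------------------------------------------------------
    n_tx_per_cell = rng.poisson(cfg.transcripts_per_cell_mean, n_cells)
    parent = np.repeat(np.arange(n_cells), n_tx_per_cell)
    n_tx = parent.size

    nuclear = rng.random(n_tx) < cfg.nuclear_fraction
    spread = np.where(nuclear, cfg.nucleus_radius, cfg.cell_radius)
    ang = rng.uniform(0, 2 * np.pi, n_tx)
    rr = spread * np.sqrt(rng.random(n_tx))
    tx_xy = xy_arr[parent] + np.c_[rr * np.cos(ang), rr * np.sin(ang)]

    # expression source: the parent cell, or (contamination) the nearest other cell
    source = parent.copy()
    if cfg.contamination_rate > 0 and n_cells > 1:
        contam = rng.random(n_tx) < cfg.contamination_rate
        nn = cKDTree(xy_arr).query(xy_arr, k=2)[1][:, 1]  # nearest other cell
        source[contam] = nn[parent[contam]]

    # gene emission: mixture of source cell-type markers and source cell's
    # niche-region vocabulary (transcript inherits the source cell's region)
    src_region = cell_region[source]
    src_type = types_arr[source]
    from_region = rng.random(n_tx) < cfg.niche_signal
    gene_idx = np.empty(n_tx, dtype=np.int64)
    for t, prof in type_profiles.items():
        m = (~from_region) & (src_type == t)
        if m.any():
            gene_idx[m] = rng.choice(len(genes), size=int(m.sum()), p=prof)
    for r, prof in region_profiles.items():
        m = from_region & (src_region == r)
        if m.any():
            gene_idx[m] = rng.choice(len(genes), size=int(m.sum()), p=prof)

    tx = pd.DataFrame(
        {
            "x_location": tx_xy[:, 0],
            "y_location": tx_xy[:, 1],
            "feature_name": np.asarray(genes, dtype=object)[gene_idx],
            "probe_class": "gene",
            "nucleus_id": pd.array(np.where(nuclear, cell_ids[parent], None), dtype="string"),
            "sample_id": cfg.sample_id,
        }
    )

    # --- control probes (blanks and negative controls) --------------------
    if cfg.blank_probe_fraction > 0:
        n_ctrl = int(round(cfg.blank_probe_fraction / (1 - cfg.blank_probe_fraction) * n_tx))
        cxy = rng.uniform([0, 0], [cfg.tissue_width, cfg.tissue_height], size=(n_ctrl, 2))
        cls = rng.choice(
            ["blank", "negative_control_probe", "negative_control_codeword"],
            size=n_ctrl,
            p=[0.7, 0.15, 0.15],
        )
        name = np.array([f"{'BLANK' if c == 'blank' else 'NegCtrl'}_{i}" for i, c in enumerate(cls)], dtype=object)
        # controls landing inside a nucleus get that nucleus id
        d, j = cKDTree(xy_arr).query(cxy)
        nid = pd.array(np.where(d <= cfg.nucleus_radius, cell_ids[j], None), dtype="string")
        ctrl = pd.DataFrame(
            {
                "x_location": cxy[:, 0],
                "y_location": cxy[:, 1],
                "feature_name": name,
                "probe_class": cls,
                "nucleus_id": nid,
                "sample_id": cfg.sample_id,
            }
        )
        tx = pd.concat([tx, ctrl], ignore_index=True)

    # --- quality values: pass / fail mixture straddling QV 20 -------------
    n_all = len(tx)
    low = rng.random(n_all) < cfg.qv_low_fraction
    qv = np.where(
        low,
        np.clip(rng.normal(14.0, 3.0, n_all), 0.0, 19.99),
        np.clip(rng.normal(32.0, 5.0, n_all), 20.0, 45.0),
    )
    tx.insert(3, "qv", qv)

    truth = SyntheticTruth(
        niche_label_transcript=np.r_[cell_region[source], np.full(n_all - n_tx, -1)],
        niche_label_cell=cell_region,
        niche_seeds=niche_seeds,
        lumen_centers=centers,
        lumen_radii=radii,
        lumen_membership={cid: li for cid, li in zip(cell_ids, lumen_of) if li > 0},
        cell_type_truth={cid: f"type_{t}" for cid, t in zip(cell_ids, types_arr)},
        lineage_truth={f"type_{t}": _lineage_of(t, cfg.n_cell_types) for t in range(cfg.n_cell_types)},
    )
    return tx, cells, truth


# ---------------------------------------------------------------------------
# airspace-level counts along a planted severity axis
# ---------------------------------------------------------------------------

def pattern_mean(pattern: str, severity: np.ndarray, base: float = 50.0, amplitude: float = 2.0) -> np.ndarray:
    """Planted mean expression (per unit exposure) of a pattern class.

    Non-flat classes are Gaussian bumps on the severity axis whose centers
    are ordered homeostatic < early < intermediate < late; ``amplitude`` is
    the peak/baseline fold change.
    """
    s = np.asarray(severity, dtype=float)
    if pattern == "flat":
        return np.full_like(s, base)
    c = PATTERN_PEAKS[pattern]
    bump = np.exp(-0.5 * ((s - c) / 0.12) ** 2)
    return base * (1.0 + (amplitude - 1.0) * bump)


def generate_airspace_counts(
    n_airspaces: int,
    n_genes: int,
    pattern_assignment: Mapping[str, str],
    seed: int,
    dispersion: float = 0.2,
    base_mean: float = 50.0,
    amplitude: float = 2.0,
    n_tmas: int = 2,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Negative-binomial airspace × gene counts around pattern-class means.

    ``pattern_assignment`` maps each gene name to one of
    :data:`PATTERN_CLASSES`; genes not listed are ``flat``. Counts are
    NB(mean = exposure × pattern mean, dispersion) where per-airspace
    exposure varies log-normally; the exposure is returned as a
    ``total_count``-like column ``_exposure`` is *not* included — library
    size is whatever the counts sum to, as in real data.

    Raises ``ValueError`` for ``n_airspaces < 10`` (too few points to fit or
    test a smooth).
    """
    if n_airspaces < 10:
        raise ValueError(f"n_airspaces must be >= 10 to support a smooth fit, got {n_airspaces}")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    gene_names = [f"g{i:04d}" for i in range(n_genes)]
    patterns = {}
    for g in gene_names:
        p = pattern_assignment.get(g, "flat")
        if p not in PATTERN_CLASSES:
            raise ValueError(f"unknown pattern class {p!r} for gene {g}")
        patterns[g] = p

    rng = np.random.default_rng(seed)
    # unique severities: evenly spaced quantile midpoints, shuffled
    severity = rng.permutation((np.arange(n_airspaces) + 0.5) / n_airspaces)
    exposure = rng.lognormal(0.0, 0.3, n_airspaces)

    counts = np.empty((n_airspaces, n_genes), dtype=np.int64)
    nb_n = 1.0 / dispersion
    for j, g in enumerate(gene_names):
        mu = pattern_mean(patterns[g], severity, base=base_mean, amplitude=amplitude) * exposure
        counts[:, j] = rng.negative_binomial(nb_n, nb_n / (nb_n + mu))

    idx = [f"as{i:04d}" for i in range(n_airspaces)]
    df = pd.DataFrame(counts, index=idx, columns=gene_names)
    df.index.name = "airspace_id"
    tma = np.array([f"TMA{1 + i % n_tmas}" for i in range(n_airspaces)])
    truth = SyntheticTruth(trajectory_truth=severity, tma=tma, de_gene_truth=patterns)
    return df, truth


# ---------------------------------------------------------------------------
# cells with a planted pairwise attraction
# ---------------------------------------------------------------------------

def generate_proximity_cells(
    n_cells: int,
    attraction: float,
    seed: int,
    pair: tuple[str, str] = ("A", "B"),
    radius: float = 60.0,
    window: float | None = None,
    sample_id: str = "synth_prox",
) -> pd.DataFrame:
    """Cells of four types where ``pair[1]`` cells are attracted to ``pair[0]``.

    ``attraction`` multiplies the *odds* that a ``pair[1]`` cell lies within
    ``radius`` µm of at least one ``pair[0]`` cell, relative to complete
    spatial randomness (attraction = 1). Only the binary near/far outcome is
    controlled, which is exactly the quantity the proximity logistic
    regression estimates, so the planted pairwise log odds ratio is
    ``log(attraction)``.
    """
    if attraction < 0:
        raise ValueError("attraction must be >= 0")
    if n_cells == 0:
        return pd.DataFrame(
            columns=["cell_id", "x", "y", "cell_type", "sample_id"]
        ).astype({"x": float, "y": float})

    rng = np.random.default_rng(seed)
    if window is None:
        window = float(np.sqrt(n_cells / 5e-4))  # ~5e-4 cells/µm² overall
    n_a = max(1, int(0.15 * n_cells))
    n_b = max(1, int(0.15 * n_cells))
    n_other = max(0, n_cells - n_a - n_b)

    a_xy = rng.uniform(0, window, size=(n_a, 2))
    a_tree = cKDTree(a_xy)

    def near_any_a(pts: np.ndarray) -> np.ndarray:
        d, _ = a_tree.query(pts, k=1)
        return d <= radius

    # baseline probability that a CSR point falls near an A cell: exact area
    # of the union of radius-discs clipped to the window
    from shapely.geometry import Point, box
    from shapely.ops import unary_union

    near_region = unary_union([Point(*c).buffer(radius, quad_segs=64) for c in a_xy])
    near_region = near_region.intersection(box(0.0, 0.0, window, window))
    p0 = float(np.clip(near_region.area / window**2, 1e-6, 1 - 1e-6))
    odds = attraction * p0 / (1 - p0)
    p_near = odds / (1 + odds)

    b_xy = np.empty((n_b, 2))
    want_near = rng.random(n_b) < p_near
    for i in range(n_b):
        while True:  # rejection sampling against the near/far region
            if want_near[i]:
                c = a_xy[rng.integers(n_a)]
                ang = rng.uniform(0, 2 * np.pi)
                rr = radius * np.sqrt(rng.random())
                p = c + [rr * np.cos(ang), rr * np.sin(ang)]
                if 0 <= p[0] <= window and 0 <= p[1] <= window:
                    b_xy[i] = p
                    break
            else:
                p = rng.uniform(0, window, 2)
                if not near_any_a(p[None, :])[0]:
                    b_xy[i] = p
                    break

    other_xy = rng.uniform(0, window, size=(n_other, 2))
    other_type = np.where(np.arange(n_other) % 2 == 0, "C", "D")

    xy = np.vstack([a_xy, b_xy, other_xy])
    ct = np.r_[np.full(n_a, pair[0]), np.full(n_b, pair[1]), other_type]
    df = pd.DataFrame(
        {
            "cell_id": [f"p{i:05d}" for i in range(len(xy))],
            "x": xy[:, 0],
            "y": xy[:, 1],
            "cell_type": ct,
            "sample_id": sample_id,
        }
    )
    return df


# ---------------------------------------------------------------------------
# output helpers
# ---------------------------------------------------------------------------

def write_transcripts(tx: pd.DataFrame, path: str, fmt: str = "csv") -> None:
    """Write a transcript table as CSV or parquet."""
    if fmt == "csv":
        tx.to_csv(path, index=False)
    elif fmt == "parquet":
        tx.to_parquet(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_truth(truth: SyntheticTruth, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(truth.to_json())
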