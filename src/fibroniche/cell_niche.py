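"""Cell-based niches from local cell-type composition.

Each cell is described by the cell-type composition of its 25 nearest
neighboring cells (within the same sample — samples are distinct tissue
cores), and k-means over those composition vectors partitions cells into
spatial niches C1..Ck, labeled by decreasing cluster size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = ["NeighborhoodComposition", "neighborhood_composition", "kmeans_niches"]


@dataclass
class NeighborhoodComposition:
    """Per-cell cell-type fractions over the k nearest neighbors."""

    cell_ids: np.ndarray
    fractions: np.ndarray      # (n_cells, n_types), rows sum to 1
    cell_types: np.ndarray     # column order


def neighborhood_composition(cells: pd.DataFrame, k_neighbors: int = 25) -> NeighborhoodComposition:
    """Cell-type composition of each cell's ``k_neighbors`` closest neighbors.

    The cell itself is excluded; neighbors never cross ``sample_id``
    boundaries. Distance ties at the cutoff resolve by cell order (the
    KD-tree returns the lower index first). Samples with at most
    ``k_neighbors`` cells use all available neighbors, with a warning.
    """
    if "cell_type" not in cells:
        raise ValueError("cells must carry a cell_type column")
    types = np.asarray(sorted(cells["cell_type"].unique()))
    tpos = pd.Series(np.arange(len(types)), index=types)
    frac = np.zeros((len(cells), len(types)))
    cell_ids = cells["cell_id"].to_numpy()
    type_idx = tpos[cells["cell_type"]].to_numpy()
    row_of = np.arange(len(cells))

    for sid, idx in cells.groupby("sample_id", sort=True).indices.items():
        idx = np.sort(idx)
        xy = cells.iloc[idx][["x", "y"]].to_numpy(dtype=float)
        k = k_neighbors
        if len(idx) <= k_neighbors:
            k = len(idx) - 1
            warnings.warn(
                f"sample {sid!r} has {len(idx)} cells; using {k} neighbors instead of {k_neighbors}",
                stacklevel=2,
            )
        if k < 1:
            continue
        _, nn = cKDTree(xy).query(xy, k=k + 1)  # self included at distance 0
        nn = np.atleast_2d(nn)[:, 1:]
        t_nn = type_idx[idx][nn]
        counts = np.zeros((len(idx), len(types)))
        np.add.at(counts, (np.repeat(np.arange(len(idx)), k), t_nn.ravel()), 1.0)
        frac[row_of[idx]] = counts / k
    return NeighborhoodComposition(cell_ids=cell_ids, fractions=frac, cell_types=types)


def kmeans_niches(comp: NeighborhoodComposition, k: int = 12, seed: int = 0) -> pd.DataFrame:
    """k-means over composition vectors; niches C1..Ck by decreasing size.

    Returns a DataFrame with ``cell_id`` and ``cell_niche``. Empty clusters
    (possible for degenerate inputs) trigger a re-seeded refit, logged.
    """
    n = comp.fractions.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} cells, got {n}")
    from sklearn.cluster import KMeans

    labels = None
    for attempt in range(5):
        km = KMeans(n_clusters=k, random_state=seed + attempt, n_init=10)
        cand = km.fit_predict(comp.fractions)
        if len(np.unique(cand)) == k:
            labels = cand
            break
        logger.warning("k-means produced an empty cluster; re-seeding (attempt %d)", attempt + 1)
    if labels is None:
        labels = cand  # degenerate data; keep last fit
    # relabel by decreasing cluster size; ties broken by original label
    sizes = np.bincount(labels, minlength=k)
    order = np.lexsort((np.arange(k), -sizes))
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(k)
    niche = np.array([f"C{r + 1}" for r in rank])[labels]
    return pd.DataFrame({"cell_id": comp.cell_ids, "cell_niche": niche})
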