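"""Transcript filtering, nuclear count matrices, cell QC and cell typing.

The platform reports every decoded transcript with µm coordinates, a gene (or
control-probe) label, a decoding quality value (QV) and, when the molecule
falls inside a segmented nucleus, the nucleus/cell identifier. Analysis uses
only high-quality gene transcripts (QV >= 20, non-control probes), and the
cell-level expression matrix counts nuclear transcripts only, which limits
cross-cell contamination relative to whole-cell segmentation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "FilterReport",
    "filter_transcripts",
    "build_count_matrix",
    "qc_filter_cells",
    "normalize_embed_cluster",
    "assign_cell_types",
]

CONTROL_CLASSES = ("negative_control_probe", "negative_control_codeword", "unassigned_codeword")


@dataclass
class FilterReport:
    """Counts of transcripts removed per reason by :func:`filter_transcripts`."""

    n_input: int = 0
    n_low_qv: int = 0
    n_control_probe: int = 0
    n_retained: int = 0
    removed_reasons: dict = field(default_factory=dict)


@dataclass
class CountMatrix:
    """Sparse cell × gene matrix of nuclear transcript counts.

    ``control_pct`` is the percentage of each cell's high-quality nuclear
    transcripts that came from negative-control probes, negative-control
    codewords or unassigned codewords (per class and cumulative), used by QC.
    """

    X: sp.csr_matrix
    cell_ids: np.ndarray
    genes: np.ndarray
    control_pct: pd.DataFrame | None = None  # index cell_id, per-class + "cumulative" columns

    @property
    def totals(self) -> np.ndarray:
        """Per-cell total nuclear transcript counts (row sums)."""
        return np.asarray(self.X.sum(axis=1)).ravel()

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def to_anndata(self):
        import anndata as ad

        return ad.AnnData(
            X=self.X.copy(),
            obs=pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id")),
            var=pd.DataFrame(index=pd.Index(self.genes, name="gene")),
        )

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        cp = self.control_pct.loc[self.cell_ids[mask]] if self.control_pct is not None else None
        return CountMatrix(self.X[mask], self.cell_ids[mask], self.genes, cp)


def filter_transcripts(
    t: pd.DataFrame, qv_min: float = 20.0, return_report: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, FilterReport]:
    """Remove low-quality transcripts (QV < ``qv_min``, strict) and all
    control probes, keeping only ``probe_class == "gene"`` rows.

    Empty input yields an empty output. With ``return_report=True`` also
    returns per-reason removal counts.
    """
    rep = FilterReport(n_input=len(t))
    if len(t) == 0:
        out = t.copy()
        return (out, rep) if return_report else out
    low = t["qv"].to_numpy() < qv_min
    nongene = (t["probe_class"] != "gene").to_numpy()
    keep = ~low & ~nongene
    rep.n_low_qv = int(low.sum())
    rep.n_control_probe = int((nongene & ~low).sum())
    rep.n_retained = int(keep.sum())
    rep.removed_reasons = {"low_qv": rep.n_low_qv, "control_probe": rep.n_control_probe}
    out = t.loc[keep]  # original index preserved so rows stay traceable
    return (out, rep) if return_report else out


def control_probe_percentages(t: pd.DataFrame, qv_min: float = 20.0) -> pd.DataFrame:
    """Per-cell control-probe percentages among high-quality nuclear transcripts.

    Computed before control probes are dropped: for each nucleus, the share
    of its QV-passing transcripts in each control class plus their cumulative
    sum, as percentages.
    """
    hq = t[(t["qv"] >= qv_min) & t["nucleus_id"].notna()]
    if len(hq) == 0:
        return pd.DataFrame(columns=[*CONTROL_CLASSES, "cumulative"])
    tab = pd.crosstab(hq["nucleus_id"], hq["probe_class"])
    for c in CONTROL_CLASSES:
        if c not in tab:
            tab[c] = 0
    pct = tab[list(CONTROL_CLASSES)].div(tab.sum(axis=1), axis=0) * 100.0
    pct["cumulative"] = pct.sum(axis=1)
    pct.index.name = "cell_id"
    return pct


def build_count_matrix(t: pd.DataFrame, cells: pd.DataFrame, all_cells: bool = True) -> CountMatrix:
    """Cell × gene counts from nuclear transcripts.

    Only rows with a ``nucleus_id`` contribute; transcripts referencing a
    nucleus absent from ``cells`` are dropped with a warning. With
    ``all_cells=True`` (default) the matrix has a row for every cell in
    ``cells`` (possibly all-zero); otherwise only cells with >= 1 nuclear
    transcript appear. Input is expected to be quality-filtered already;
    control-probe percentages should be computed beforehand on the raw table
    (see :func:`control_probe_percentages`).
    """
    cell_ids = cells["cell_id"].to_numpy()
    if len(np.unique(cell_ids)) != len(cell_ids):
        raise ValueError("cell_id values must be unique")
    nuc = t[t["nucleus_id"].notna()]
    known = nuc["nucleus_id"].isin(cell_ids).to_numpy()
    if not known.all():
        n_bad = int((~known).sum())
        warnings.warn(f"{n_bad} nuclear transcripts reference unknown cells; dropped", stacklevel=2)
        nuc = nuc.loc[known]
    genes = np.asarray(sorted(t.loc[t["probe_class"] == "gene", "feature_name"].unique()))
    if not all_cells:
        cell_ids = np.asarray(sorted(nuc["nucleus_id"].unique()))
    cell_pos = pd.Series(np.arange(len(cell_ids)), index=cell_ids)
    gene_pos = pd.Series(np.arange(len(genes)), index=genes)
    keep = nuc["feature_name"].isin(gene_pos.index)
    nuc = nuc.loc[keep]
    rows = cell_pos[nuc["nucleus_id"]].to_numpy()
    cols = gene_pos[nuc["feature_name"]].to_numpy()
    X = sp.coo_matrix(
        (np.ones(len(nuc), dtype=np.int64), (rows, cols)), shape=(len(cell_ids), len(genes))
    ).tocsr()
    return CountMatrix(X=X, cell_ids=np.asarray(cell_ids), genes=genes)


def qc_filter_cells(
    m: CountMatrix,
    cells: pd.DataFrame,
    min_transcripts: int = 12,
    min_genes: int = 10,
    max_control_pct: float = 5.0,
    area_min: float = 6.0,
    area_max: float = 80.0,
    return_log: bool = False,
):
    """Retain cells passing all three QC rules.

    A cell is kept when it has >= ``min_transcripts`` nuclear transcripts
    covering >= ``min_genes`` unique genes; each control-probe class and
    their cumulative percentage are <= ``max_control_pct``; and its nucleus
    area lies in [``area_min``, ``area_max``] (the platform's area column;
    unit convention is the caller's). Removal reasons per cell are returned
    with ``return_log=True``.
    """
    cells = cells.set_index("cell_id").loc[m.cell_ids].reset_index()
    totals = m.totals
    n_genes = np.asarray((m.X > 0).sum(axis=1)).ravel()
    ok_counts = (totals >= min_transcripts) & (n_genes >= min_genes)

    if m.control_pct is not None and len(m.control_pct):
        cp = m.control_pct.reindex(m.cell_ids).fillna(0.0)
        ok_ctrl = (cp <= max_control_pct).all(axis=1).to_numpy()
    else:
        ok_ctrl = np.ones(len(m.cell_ids), dtype=bool)

    area = cells["nucleus_area"].to_numpy()
    ok_area = (area >= area_min) & (area <= area_max)

    keep = ok_counts & ok_ctrl & ok_area
    log = pd.DataFrame(
        {
            "cell_id": m.cell_ids,
            "fail_counts": ~ok_counts,
            "fail_controls": ~ok_ctrl,
            "fail_area": ~ok_area,
            "retained": keep,
        }
    )
    logger.info("cell QC: retained %d/%d cells", int(keep.sum()), len(keep))
    out_m = m.subset_cells(keep)
    out_c = cells.loc[keep].reset_index(drop=True)
    return (out_m, out_c, log) if return_log else (out_m, out_c)


def normalize_embed_cluster(
    m: CountMatrix,
    n_pcs: int = 20,
    resolution: float = 1.0,
    seed: int = 0,
    method: str = "leiden",
    n_neighbors: int = 15,
):
    """log1p-normalize, embed with PCA and cluster on a kNN graph.

    ``method`` is ``"leiden"`` (community detection, preferred) or
    ``"kmeans"`` (with ``resolution`` reinterpreted as the cluster count).
    Returns ``(embedding, labels)`` with one integer label per cell.
    """
    import scanpy as sc

    ad = m.to_anndata()
    ad.X = ad.X.astype(np.float32)
    sc.pp.log1p(ad)
    max_pcs = min(ad.n_obs - 1, ad.n_vars - 1)
    if n_pcs > max_pcs:
        warnings.warn(f"n_pcs={n_pcs} exceeds data rank; reduced to {max_pcs}", stacklevel=2)
        n_pcs = max_pcs
    sc.pp.pca(ad, n_comps=n_pcs, random_state=seed)
    emb = np.asarray(ad.obsm["X_pca"])
    if method == "leiden":
        sc.pp.neighbors(ad, n_neighbors=n_neighbors, random_state=seed)
        sc.tl.leiden(ad, resolution=resolution, random_state=seed, flavor="igraph", n_iterations=2)
        labels = ad.obs["leiden"].astype(int).to_numpy()
    elif method == "kmeans":
        from sklearn.cluster import KMeans

        labels = KMeans(n_clusters=int(resolution), random_state=seed, n_init=10).fit_predict(emb)
    else:
        raise ValueError(f"unknown method {method!r}")
    return emb, labels


def assign_cell_types(
    m: CountMatrix,
    reference_profiles: pd.DataFrame,
    lineage_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Assign each cell the reference profile with maximal Pearson
    correlation on log1p counts.

    ``reference_profiles`` is a type × gene table of mean expression; genes
    are intersected with the panel. All-zero cells are labeled
    ``"unassignable"``. Returns a DataFrame with ``cell_id``, ``cell_type``
    and (when ``lineage_map`` is given) ``lineage``.
    """
    if m.shape[0] == 0:
        return pd.DataFrame(columns=["cell_id", "cell_type", "lineage"])
    common = [g for g in m.genes if g in reference_profiles.columns]
    if not common:
        raise ValueError("reference profiles share no genes with the count matrix")
    gi = pd.Series(np.arange(len(m.genes)), index=m.genes)[common].to_numpy()
    X = np.log1p(np.asarray(m.X[:, gi].todense(), dtype=float))
    P = np.log1p(reference_profiles[common].to_numpy(dtype=float))

    Xc = X - X.mean(axis=1, keepdims=True)
    Pc = P - P.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(Xc, axis=1)
    pn = np.linalg.norm(Pc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Xc @ Pc.T) / np.outer(xn, pn)
    corr = np.nan_to_num(corr, nan=-np.inf)
    best = corr.argmax(axis=1)
    types = reference_profiles.index.to_numpy()[best].astype(object)
    types[X.sum(axis=1) == 0] = "unassignable"
    out = pd.DataFrame({"cell_id": m.cell_ids, "cell_type": types})
    if lineage_map is not None:
        out["lineage"] = out["cell_type"].map(lineage_map).fillna("unknown")
    return out
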