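"""Cell-segmentation-free niche discovery from transcript positions.

Transcripts of one sample form a spatial graph (edges between transcripts
closer than ``d`` µm, strict). A two-hop neighborhood-aggregation embedding
(GraphSAGE-style: sampled mean aggregation, trained unsupervised by link
prediction on positive/negative node pairs) maps every transcript to a
50-dimensional vector that summarizes its local gene composition; a Gaussian
mixture over those vectors defines transcript niches T1..Tk. Hexagonal-bin
majority maps summarize the labels spatially, and cells inherit the label of
their nearest retained bin.

The embedding model is implemented here in NumPy: mean aggregators with a
ReLU nonlinearity after the first hop and a linear second hop, L2-normalized
outputs, and a calibrated dot product scoring node pairs, trained with Adam
on a binary cross-entropy link-prediction loss. Inference uses full (unsampled) mean aggregation via
sparse matrix products, so identical neighborhoods map to identical vectors
and a frozen model projects new samples into the existing niche space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptGraph",
    "EmbeddingConfig",
    "EmbeddingModel",
    "NicheModel",
    "HexbinMap",
    "build_transcript_graph",
    "train_embedding",
    "embed_nodes",
    "fit_niche_model",
    "hexbin_map",
    "assign_cells_to_transcript_niches",
]


# ---------------------------------------------------------------------------
# transcript graph
# ---------------------------------------------------------------------------

@dataclass
class TranscriptGraph:
    """Spatial graph over one sample's retained transcripts.

    Node features are the one-hot encoding of each node's gene, stored
    implicitly as ``gene_idx`` into ``vocabulary``. ``adj`` is the symmetric
    adjacency (no self loops). ``source_rows`` are the row positions of the
    surviving nodes in the table the graph was built from.
    """

    xy: np.ndarray
    gene_idx: np.ndarray
    vocabulary: np.ndarray
    adj: sp.csr_matrix
    source_rows: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.gene_idx)

    @property
    def n_edges(self) -> int:
        return self.adj.nnz // 2

    def edges(self) -> np.ndarray:
        """Undirected edge list as an (m, 2) array with row < col."""
        coo = sp.triu(self.adj, k=1).tocoo()
        return np.column_stack([coo.row, coo.col])

    def degrees(self) -> np.ndarray:
        return np.diff(self.adj.indptr)


def build_transcript_graph(
    t: pd.DataFrame,
    d: float = 3.0,
    min_component: int = 10,
    vocabulary: np.ndarray | None = None,
) -> TranscriptGraph:
    """Build the spatial transcript graph of one sample.

    Edges connect transcripts with Euclidean distance strictly below ``d``
    µm; connected components with fewer than ``min_component`` nodes are
    removed. ``vocabulary`` fixes the gene -> feature index mapping so graphs
    from different samples share an embedding space (default: sorted unique
    genes of this table).
    """
    xy = t[["x_location", "y_location"]].to_numpy(dtype=float)
    genes = t["feature_name"].to_numpy()
    if vocabulary is None:
        vocabulary = np.asarray(sorted(pd.unique(genes)))
    vocab_pos = pd.Series(np.arange(len(vocabulary)), index=vocabulary)
    unknown = ~pd.Index(genes).isin(vocab_pos.index)
    if unknown.any():
        raise ValueError(
            f"{int(unknown.sum())} transcripts carry genes outside the vocabulary, "
            f"e.g. {genes[unknown][0]!r}"
        )
    gene_idx = vocab_pos[genes].to_numpy()

    n = len(xy)
    if n == 0:
        return TranscriptGraph(
            xy=xy, gene_idx=gene_idx, vocabulary=vocabulary,
            adj=sp.csr_matrix((0, 0)), source_rows=np.arange(0),
        )
    pairs = cKDTree(xy).query_pairs(r=d, output_type="ndarray")
    if len(pairs):
        # query_pairs uses <= r; the edge rule is strict <
        dist = np.hypot(*(xy[pairs[:, 0]] - xy[pairs[:, 1]]).T)
        pairs = pairs[dist < d]
    rows = np.r_[pairs[:, 0], pairs[:, 1]] if len(pairs) else np.array([], dtype=int)
    cols = np.r_[pairs[:, 1], pairs[:, 0]] if len(pairs) else np.array([], dtype=int)
    adj = sp.coo_matrix((np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n)).tocsr()

    n_comp, comp = sp.csgraph.connected_components(adj, directed=False)
    sizes = np.bincount(comp, minlength=n_comp)
    keep = sizes[comp] >= min_component
    idx = np.flatnonzero(keep)
    adj = adj[idx][:, idx]
    logger.info(
        "transcript graph: %d/%d nodes kept (%d components pruned), %d edges",
        len(idx), n, int((sizes < min_component).sum()), adj.nnz // 2,
    )
    return TranscriptGraph(
        xy=xy[idx], gene_idx=gene_idx[idx], vocabulary=vocabulary, adj=adj, source_rows=idx
    )


# ---------------------------------------------------------------------------
# embedding model
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingConfig:
    """Architecture and training configuration of the embedding model."""

    sample_sizes: tuple[int, int] = (20, 10)   # neighbors sampled at hop 1 / hop 2
    dims: tuple[int, int] = (50, 50)           # embedding width per hop
    epochs: int = 10
    n_root_nodes: int = 5000                   # root-node subsample per sample graph
    batch_pairs: int = 512
    max_pairs_per_epoch: int = 50_000          # cap on positive pairs drawn per epoch
    learning_rate: float = 5e-3
    holdout_fraction: float = 0.05             # edges held out for link-prediction accuracy


@dataclass
class EmbeddingModel:
    """Fitted two-hop mean-aggregation embedding."""

    cfg: EmbeddingConfig
    vocabulary: np.ndarray
    params: dict[str, np.ndarray] = field(default_factory=dict)
    train_accuracy: float = float("nan")
    holdout_accuracy: float = float("nan")

    def weights_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for k in sorted(self.params):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.params[k]).tobytes())
        return h.hexdigest()


def _init_params(cfg: EmbeddingConfig, n_genes: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    d1, d2 = cfg.dims
    g = lambda *s: (rng.standard_normal(s) * np.sqrt(2.0 / s[-1])).astype(np.float64)
    return {
        "Ws1": g(d1, n_genes), "Wn1": g(d1, n_genes), "b1": np.zeros(d1),
        "Ws2": g(d2, d1), "Wn2": g(d2, d1), "b2": np.zeros(d2),
        "a": np.array([5.0]), "c": np.array([0.0]),
    }


def _sample_neighbors(adj: sp.csr_matrix, nodes: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Sample k neighbors (with replacement) per node; isolated nodes fall
    back to themselves."""
    indptr, indices = adj.indptr, adj.indices
    deg = indptr[nodes + 1] - indptr[nodes]
    safe = np.maximum(deg, 1)
    offs = (rng.random((len(nodes), k)) * safe[:, None]).astype(np.int64)
    out = indices[np.minimum(indptr[nodes, None] + offs, len(indices) - 1)]
    iso = deg == 0
    if iso.any():
        out[iso] = nodes[iso, None]
    return out


def _forward_batch(params, adj, gene_idx, n_genes, batch_nodes, cfg, rng):
    """Sampled two-hop forward pass for the unique endpoint nodes of a batch.

    Returns normalized embeddings plus the cache needed for backprop.
    """
    s1, s2 = cfg.sample_sizes
    nb = len(batch_nodes)
    neigh2 = _sample_neighbors(adj, batch_nodes, s2, rng)          # (nb, s2)
    U, inv = np.unique(np.r_[batch_nodes, neigh2.ravel()], return_inverse=True)
    inv_B, inv_n2 = inv[:nb], inv[nb:].reshape(nb, s2)
    nu = len(U)

    neigh1 = _sample_neighbors(adj, U, s1, rng)                    # (nu, s1)
    C1 = np.zeros((nu, n_genes))                                   # hop-1 neighbor gene counts
    np.add.at(C1, (np.repeat(np.arange(nu), s1), gene_idx[neigh1].ravel()), 1.0)
    C1 /= s1
    gU = gene_idx[U]
    pre1 = params["Ws1"].T[gU] + C1 @ params["Wn1"].T + params["b1"]
    h1 = np.maximum(pre1, 0.0)                                     # (nu, d1)

    h1_B = h1[inv_B]
    m2 = h1[inv_n2].mean(axis=1)                                   # (nb, d1)
    pre2 = h1_B @ params["Ws2"].T + m2 @ params["Wn2"].T + params["b2"]
    h2 = pre2
    nrm = np.linalg.norm(h2, axis=1, keepdims=True)
    nrm = np.maximum(nrm, 1e-12)
    z = h2 / nrm
    cache = dict(C1=C1, gU=gU, pre1=pre1, h1=h1, inv_B=inv_B, inv_n2=inv_n2,
                 h1_B=h1_B, m2=m2, pre2=pre2, h2=h2, nrm=nrm, z=z, nu=nu, s2=s2)
    return z, cache


def _backward_batch(params, cache, dz, n_genes):
    """Backprop from embedding gradients ``dz`` to parameter gradients."""
    z, h2, nrm = cache["z"], cache["h2"], cache["nrm"]
    dh2 = (dz - z * (dz * z).sum(axis=1, keepdims=True)) / nrm
    d2 = dh2

    grads = {
        "Ws2": d2.T @ cache["h1_B"],
        "Wn2": d2.T @ cache["m2"],
        "b2": d2.sum(axis=0),
    }
    dh1 = np.zeros_like(cache["h1"])
    np.add.at(dh1, cache["inv_B"], d2 @ params["Ws2"])
    dn = (d2 @ params["Wn2"]) / cache["s2"]
    np.add.at(dh1, cache["inv_n2"].ravel(), np.repeat(dn, cache["s2"], axis=0))
    d1 = dh1 * (cache["pre1"] > 0)

    gWs1 = np.zeros((n_genes, params["Ws1"].shape[0]))
    np.add.at(gWs1, cache["gU"], d1)
    grads["Ws1"] = gWs1.T
    grads["Wn1"] = d1.T @ cache["C1"]
    grads["b1"] = d1.sum(axis=0)
    return grads


def _pair_loss_grad(z, pi, pj, y, a, c):
    """BCE loss on calibrated dot products; returns loss, accuracy, dz, da, dc."""
    s = (z[pi] * z[pj]).sum(axis=1)
    logit = a * s + c
    p = 1.0 / (1.0 + np.exp(-logit))
    eps = 1e-12
    loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
    acc = float(((logit > 0) == (y > 0.5)).mean())
    g = (p - y) / len(y)
    dz = np.zeros_like(z)
    np.add.at(dz, pi, (g * a)[:, None] * z[pj])
    np.add.at(dz, pj, (g * a)[:, None] * z[pi])
    return loss, acc, dz, float(g @ s), float(g.sum())


def _training_subgraph(g: TranscriptGraph, n_roots: int, rng: np.random.Generator) -> np.ndarray:
    """Node set: sampled root nodes plus their three-hop neighbors."""
    n = g.n_nodes
    roots = rng.choice(n, size=min(n_roots, n), replace=False)
    frontier = np.zeros(n, dtype=bool)
    frontier[roots] = True
    reached = frontier.copy()
    for _ in range(3):
        nxt = (g.adj @ frontier.astype(np.int8)) > 0
        frontier = nxt & ~reached
        reached |= nxt
        if not frontier.any():
            break
    return np.flatnonzero(reached)


def train_embedding(
    graphs: list[TranscriptGraph],
    cfg: EmbeddingConfig | None = None,
    seed: int = 0,
) -> EmbeddingModel:
    """Train the embedding by link prediction on a joined training graph.

    From each sample graph, ``n_root_nodes`` roots and their three-hop
    neighbors form a training subgraph; the joined subgraphs supply positive
    node pairs (existing edges) matched 1:1 with uniformly sampled negative
    pairs. A held-out edge fraction gives the reported link-prediction
    accuracy. Raises ``ValueError`` when no graph contributes an edge.
    """
    cfg = cfg or EmbeddingConfig()
    if not graphs:
        raise ValueError("no graphs supplied")
    vocab = graphs[0].vocabulary
    for g in graphs[1:]:
        if not np.array_equal(g.vocabulary, vocab):
            raise ValueError("all graphs must share the same gene vocabulary")
    rng = np.random.default_rng(seed)

    # join the per-sample training subgraphs into one block-diagonal graph
    blocks, genes_parts = [], []
    for g in graphs:
        nodes = _training_subgraph(g, cfg.n_root_nodes, rng)
        blocks.append(g.adj[nodes][:, nodes])
        genes_parts.append(g.gene_idx[nodes])
    adj = sp.block_diag(blocks, format="csr")
    gene_idx = np.concatenate(genes_parts)
    n_genes = len(vocab)

    edges = sp.triu(adj, k=1).tocoo()
    edges = np.column_stack([edges.row, edges.col])
    if len(edges) == 0:
        raise ValueError("training graph has no edges; cannot form positive pairs")
    perm = rng.permutation(len(edges))
    n_hold = max(1, int(cfg.holdout_fraction * len(edges)))
    hold_edges, train_edges = edges[perm[:n_hold]], edges[perm[n_hold:]]
    if len(train_edges) == 0:
        train_edges = hold_edges

    params = _init_params(cfg, n_genes, rng)
    mom = {k: np.zeros_like(v) for k, v in params.items()}
    vel = {k: np.zeros_like(v) for k, v in params.items()}
    step = 0
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
    n_nodes = adj.shape[0]
    last_acc = float("nan")

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_edges))[: cfg.max_pairs_per_epoch]
        accs, losses = [], []
        for lo in range(0, len(order), cfg.batch_pairs):
            pos = train_edges[order[lo: lo + cfg.batch_pairs]]
            neg = rng.integers(0, n_nodes, size=pos.shape)
            pairs = np.vstack([pos, neg])
            y = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
            nodes, inv = np.unique(pairs, return_inverse=True)
            pi, pj = inv.reshape(pairs.shape).T

            z, cache = _forward_batch(params, adj, gene_idx, n_genes, nodes, cfg, rng)
            loss, acc, dz, da, dc = _pair_loss_grad(
                z, pi, pj, y, float(params["a"][0]), float(params["c"][0])
            )
            grads = _backward_batch(params, cache, dz, n_genes)
            grads["a"] = np.array([da])
            grads["c"] = np.array([dc])
            step += 1
            for k in params:
                gk = grads[k]
                mom[k] = beta1 * mom[k] + (1 - beta1) * gk
                vel[k] = beta2 * vel[k] + (1 - beta2) * gk * gk
                mhat = mom[k] / (1 - beta1**step)
                vhat = vel[k] / (1 - beta2**step)
                params[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + adam_eps)
            accs.append(acc)
            losses.append(loss)
        last_acc = float(np.mean(accs))
        logger.info("embedding epoch %d: loss %.4f, train accuracy %.3f",
                    epoch + 1, float(np.mean(losses)), last_acc)

    # held-out link-prediction accuracy with frozen weights
    neg = rng.integers(0, n_nodes, size=hold_edges.shape)
    pairs = np.vstack([hold_edges, neg])
    y = np.r_[np.ones(len(hold_edges)), np.zeros(len(neg))]
    nodes, inv = np.unique(pairs, return_inverse=True)
    pi, pj = inv.reshape(pairs.shape).T
    z, _ = _forward_batch(params, adj, gene_idx, n_genes, nodes, cfg, rng)
    _, hold_acc, *_ = _pair_loss_grad(z, pi, pj, y, float(params["a"][0]), float(params["c"][0]))

    model = EmbeddingModel(cfg=cfg, vocabulary=vocab, params=params,
                           train_accuracy=last_acc, holdout_accuracy=hold_acc)
    logger.info("embedding trained: train acc %.3f, held-out acc %.3f", last_acc, hold_acc)
    return model


def embed_nodes(model: EmbeddingModel, g: TranscriptGraph) -> np.ndarray:
    """Embed every node of ``g`` with frozen weights and full (unsampled)
    mean aggregation.

    Raises ``ValueError`` when the graph's vocabulary is not the model's.
    """
    if not np.array_equal(g.vocabulary, model.vocabulary):
        raise ValueError("graph vocabulary differs from the model's training vocabulary")
    p = model.params
    n, n_genes = g.n_nodes, len(model.vocabulary)
    if n == 0:
        return np.zeros((0, model.cfg.dims[1]))
    X = sp.csr_matrix(
        (np.ones(n), (np.arange(n), g.gene_idx)), shape=(n, n_genes)
    )
    deg = np.maximum(g.degrees(), 1).astype(float)
    Anorm = sp.diags(1.0 / deg) @ g.adj.astype(float)

    h1 = np.maximum(p["Ws1"].T[g.gene_idx] + (Anorm @ X) @ p["Wn1"].T + p["b1"], 0.0)
    h2 = h1 @ p["Ws2"].T + (Anorm @ h1) @ p["Wn2"].T + p["b2"]
    nrm = np.maximum(np.linalg.norm(h2, axis=1, keepdims=True), 1e-12)
    return h2 / nrm


# ---------------------------------------------------------------------------
# Gaussian-mixture niches
# ---------------------------------------------------------------------------

@dataclass
class NicheModel:
    """Gaussian mixture over embeddings defining transcript niches T1..Tk."""

    gmm: object
    k: int

    @property
    def labels_(self) -> np.ndarray:
        return np.array([f"T{i + 1}" for i in range(self.k)])

    def classify(self, emb: np.ndarray) -> np.ndarray:
        """Hard labels T1..Tk for each embedding row."""
        return self.labels_[self.gmm.predict(emb)]

    def responsibilities(self, emb: np.ndarray) -> np.ndarray:
        return self.gmm.predict_proba(emb)


def fit_niche_model(
    emb: np.ndarray,
    k: int = 12,
    seed: int = 0,
    max_fit_rows: int = 50_000,
    reg_covar: float = 1e-6,
    n_init: int = 10,
) -> NicheModel:
    """Fit a k-component full-covariance Gaussian mixture to the embeddings.

    For very large inputs the mixture is fitted on a uniform row subsample
    (``max_fit_rows``) and used to classify all rows. k-means++ initialization
    with a fixed seed; a small diagonal ridge keeps covariances
    positive-definite.
    """
    if emb.shape[0] < k:
        raise ValueError(f"need at least k={k} rows, got {emb.shape[0]}")
    from sklearn.mixture import GaussianMixture

    rng = np.random.default_rng(seed)
    fit_emb = emb
    if emb.shape[0] > max_fit_rows:
        fit_emb = emb[rng.choice(emb.shape[0], size=max_fit_rows, replace=False)]
    gmm = GaussianMixture(
        n_components=k, covariance_type="full", reg_covar=reg_covar,
        init_params="k-means++", random_state=seed, max_iter=200, n_init=n_init,
    ).fit(fit_emb)
    if not gmm.converged_:
        logger.warning("Gaussian mixture did not converge in %d iterations", 200)
    return NicheModel(gmm=gmm, k=k)


# ---------------------------------------------------------------------------
# hexbin maps and cell assignment
# ---------------------------------------------------------------------------

@dataclass
class HexbinMap:
    """Hexagonal-bin majority-label summary of labeled transcripts.

    Flat-top hexagons; ``bin_width`` is the horizontal pitch between adjacent
    bin-center columns. Bins with fewer than the minimum transcript count are
    dropped. Majority ties break toward the lowest niche index, and bins are
    ordered by axial coordinates so nearest-bin queries are reproducible.
    """

    centers: np.ndarray          # (n_bins, 2) µm
    labels: np.ndarray           # majority niche label per bin
    counts: np.ndarray           # transcripts per bin
    axial: np.ndarray            # (n_bins, 2) integer axial coordinates
    bin_width: float


def _hex_assign(xy: np.ndarray, bin_width: float) -> np.ndarray:
    """Axial coordinates of the flat-top hexagon containing each point.

    Hexagon circumradius R = 2/3 * pitch so adjacent column centers are
    ``bin_width`` apart; cube-rounding gives exact point-in-hexagon binning.
    """
    R = bin_width * 2.0 / 3.0
    x, y = xy[:, 0] / R, xy[:, 1] / R
    q = (2.0 / 3.0) * x
    r = (-1.0 / 3.0) * x + (np.sqrt(3.0) / 3.0) * y
    # cube rounding
    s = -q - r
    rq, rr, rs = np.round(q), np.round(r), np.round(s)
    dq, dr, ds = np.abs(rq - q), np.abs(rr - r), np.abs(rs - s)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    rq = np.where(fix_q, -rr - rs, rq)
    rr = np.where(fix_r, -rq - rs, rr)
    return np.column_stack([rq, rr]).astype(np.int64)


def _hex_centers(axial: np.ndarray, bin_width: float) -> np.ndarray:
    R = bin_width * 2.0 / 3.0
    q, r = axial[:, 0].astype(float), axial[:, 1].astype(float)
    return np.column_stack([R * 1.5 * q, R * np.sqrt(3.0) * (r + q / 2.0)])


def hexbin_map(
    t: pd.DataFrame, labels: np.ndarray, bin_width: float = 5.0, min_bin: int = 10
) -> HexbinMap:
    """Summarize labeled transcripts into a majority-label hexbin map.

    ``labels`` are niche labels (e.g. ``"T3"``) aligned with the rows of
    ``t``. Bins with fewer than ``min_bin`` transcripts are dropped; majority
    ties break toward the lowest label index.
    """
    xy = t[["x_location", "y_location"]].to_numpy(dtype=float)
    labels = np.asarray(labels)
    if len(labels) != len(xy):
        raise ValueError("labels must align with transcript rows")
    if len(xy) == 0:
        return HexbinMap(np.zeros((0, 2)), np.array([], dtype=object),
                         np.array([], dtype=int), np.zeros((0, 2), dtype=int), bin_width)
    axial = _hex_assign(xy, bin_width)
    uniq_lab = np.asarray(sorted(pd.unique(labels), key=lambda s: (len(str(s)), str(s))))
    lab_idx = pd.Series(np.arange(len(uniq_lab)), index=uniq_lab)[labels].to_numpy()
    keys, bin_of = np.unique(axial, axis=0, return_inverse=True)
    counts = np.bincount(bin_of, minlength=len(keys))
    tab = np.zeros((len(keys), len(uniq_lab)), dtype=np.int64)
    np.add.at(tab, (bin_of, lab_idx), 1)
    maj = tab.argmax(axis=1)  # argmax takes the lowest index on ties
    keep = counts >= min_bin
    # deterministic bin order: sort retained bins by axial coordinates
    order = np.lexsort((keys[keep][:, 1], keys[keep][:, 0]))
    keys_k = keys[keep][order]
    return HexbinMap(
        centers=_hex_centers(keys_k, bin_width),
        labels=uniq_lab[maj[keep][order]],
        counts=counts[keep][order],
        axial=keys_k,
        bin_width=bin_width,
    )


def assign_cells_to_transcript_niches(cells: pd.DataFrame, hmap: HexbinMap) -> pd.DataFrame:
    """Give every cell the label of its nearest retained hexbin centroid.

    Equidistant bins resolve to the lowest bin index in the map's
    deterministic (axial-sorted) order. With no retained bins all cells are
    flagged ``"unassigned"``.
    """
    out = cells[["cell_id"]].copy()
    if len(hmap.centers) == 0:
        out["transcript_niche"] = "unassigned"
        return out
    xy = cells[["x", "y"]].to_numpy(dtype=float)
    _, j = cKDTree(hmap.centers).query(xy)
    out["transcript_niche"] = hmap.labels[j]
    return out
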