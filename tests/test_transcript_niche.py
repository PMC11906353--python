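"""Transcript graph, embedding, mixture niches, hexbin maps."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from fibroniche import transcript_niche as tn

from conftest import make_transcripts


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def test_edge_threshold_is_strict():
    t = make_transcripts([0.0, 2.9], [0.0, 0.0])
    g = tn.build_transcript_graph(t, d=3.0, min_component=1)
    assert g.n_edges == 1
    t2 = make_transcripts([0.0, 3.0], [0.0, 0.0])
    g2 = tn.build_transcript_graph(t2, d=3.0, min_component=1)
    assert g2.n_edges == 0


def test_small_components_pruned():
    # 9-node tight clique far from a 12-node chain: clique removed
    clique = make_transcripts(np.linspace(0, 1.6, 9), np.zeros(9))
    chain = make_transcripts(1000 + 2.0 * np.arange(12), np.zeros(12))
    g = tn.build_transcript_graph(pd.concat([clique, chain], ignore_index=True), d=3.0)
    assert g.n_nodes == 12
    assert (g.source_rows >= 9).all()


def test_graph_matches_brute_force():
    rng = np.random.default_rng(0)
    xy = rng.uniform(0, 50, size=(500, 2))
    t = make_transcripts(xy[:, 0], xy[:, 1])
    g = tn.build_transcript_graph(t, d=3.0, min_component=1)
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    expect = {(i, j) for i in range(500) for j in range(i + 1, 500) if d2[i, j] < 9.0}
    got = {tuple(sorted((g.source_rows[i], g.source_rows[j]))) for i, j in g.edges()}
    assert got == expect
    # symmetry and degree agreement
    assert (g.adj != g.adj.T).nnz == 0
    deg_bf = np.zeros(500, dtype=int)
    for i, j in expect:
        deg_bf[i] += 1
        deg_bf[j] += 1
    assert np.array_equal(g.degrees(), deg_bf[g.source_rows])


def test_empty_input_gives_empty_graph():
    g = tn.build_transcript_graph(make_transcripts([], []), d=3.0)
    assert g.n_nodes == 0


def test_unknown_gene_rejected():
    t = make_transcripts([0, 1], [0, 0], gene=["G1", "G2"])
    with pytest.raises(ValueError, match="outside the vocabulary"):
        tn.build_transcript_graph(t, vocabulary=np.array(["G1"]))


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

def _two_region_strip(n_side=3000, seed=0):
    """Two abutting regions with disjoint vocabularies."""
    rng = np.random.default_rng(seed)
    left = rng.uniform([0, 0], [100, 100], size=(n_side, 2))
    right = rng.uniform([100, 0], [200, 100], size=(n_side, 2))
    genes = np.r_[
        rng.choice([f"L{i}" for i in range(5)], n_side),
        rng.choice([f"R{i}" for i in range(5)], n_side),
    ]
    xy = np.vstack([left, right])
    t = make_transcripts(xy[:, 0], xy[:, 1], gene=genes)
    labels = np.r_[np.zeros(n_side, dtype=int), np.ones(n_side, dtype=int)]
    return t, labels


def test_training_separates_planted_regions():
    from sklearn.metrics import silhouette_score

    t, labels = _two_region_strip()
    g = tn.build_transcript_graph(t, d=3.0)
    cfg = tn.EmbeddingConfig(epochs=3, max_pairs_per_epoch=10_000)
    model = tn.train_embedding([g], cfg, seed=0)
    assert model.holdout_accuracy >= 0.7
    emb = tn.embed_nodes(model, g)
    lab = labels[g.source_rows]
    assert silhouette_score(emb[::5], lab[::5]) > 0


def test_training_requires_edges():
    t = make_transcripts([0, 100], [0, 0])
    g = tn.build_transcript_graph(t, d=3.0, min_component=1)
    with pytest.raises(ValueError, match="no edges"):
        tn.train_embedding([g], tn.EmbeddingConfig(epochs=1), seed=0)


def test_frozen_weights_unchanged_by_inference():
    t, _ = _two_region_strip(n_side=800)
    g = tn.build_transcript_graph(t, d=3.0)
    model = tn.train_embedding([g], tn.EmbeddingConfig(epochs=1, max_pairs_per_epoch=2000), seed=0)
    h0 = model.weights_hash()
    tn.embed_nodes(model, g)
    assert model.weights_hash() == h0


def test_identical_neighborhoods_get_identical_embeddings():
    """Two nodes with the same gene and the same neighbor genes embed
    identically under full (unsampled) aggregation."""
    # two separated dumbbells with identical local structure
    t = make_transcripts(
        [0.0, 1.0, 2.0, 50.0, 51.0, 52.0],
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        gene=["G1", "G2", "G1", "G1", "G2", "G1"],
    )
    g = tn.build_transcript_graph(t, d=1.5, min_component=1)
    model = tn.train_embedding([g], tn.EmbeddingConfig(epochs=1, max_pairs_per_epoch=100), seed=1)
    emb = tn.embed_nodes(model, g)
    np.testing.assert_allclose(emb[1], emb[4], atol=1e-12)
    np.testing.assert_allclose(emb[0], emb[3], atol=1e-12)


def test_full_aggregation_equals_hand_computed_frequencies():
    """With identity-like weights, hop-1 mean aggregation of one-hot features
    reproduces the neighborhood gene frequency vector (5-node line graph)."""
    t = make_transcripts(
        [0.0, 1.0, 2.0, 3.0, 4.0], [0.0] * 5,
        gene=["G1", "G2", "G1", "G3", "G2"],
    )
    g = tn.build_transcript_graph(t, d=1.5, min_component=1)
    G = len(g.vocabulary)  # G1, G2, G3
    cfg = tn.EmbeddingConfig(dims=(G, G))
    model = tn.EmbeddingModel(cfg=cfg, vocabulary=g.vocabulary, params={
        "Ws1": np.zeros((G, G)), "Wn1": np.eye(G), "b1": np.zeros(G),
        "Ws2": np.eye(G), "Wn2": np.zeros((G, G)), "b2": np.zeros(G),
        "a": np.array([1.0]), "c": np.array([0.0]),
    })
    emb = tn.embed_nodes(model, g)
    # node 2 (gene G1) has neighbors G2 and G3 -> frequencies (0, .5, .5), normalized
    expect = np.array([0.0, 0.5, 0.5])
    np.testing.assert_allclose(emb[2], expect / np.linalg.norm(expect), atol=1e-12)
    # node 0 has single neighbor G2 -> e_{G2}
    np.testing.assert_allclose(emb[0], [0.0, 1.0, 0.0], atol=1e-12)


def test_embedding_requires_matching_vocabulary():
    t, _ = _two_region_strip(n_side=1500)
    g = tn.build_transcript_graph(t, d=3.0)
    model = tn.train_embedding([g], tn.EmbeddingConfig(epochs=1, max_pairs_per_epoch=1000), seed=0)
    other = tn.build_transcript_graph(
        make_transcripts([0, 1, 2] * 4, np.repeat([0, 1, 2, 3], 3), gene="XX"),
        d=3.0, min_component=1,
    )
    with pytest.raises(ValueError, match="vocabulary"):
        tn.embed_nodes(model, other)


# ---------------------------------------------------------------------------
# Gaussian mixture niches
# ---------------------------------------------------------------------------

def test_gmm_recovers_separated_gaussians():
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(0)
    a = rng.normal(0, 0.3, size=(300, 5))
    b = rng.normal(5, 0.3, size=(300, 5))
    emb = np.vstack([a, b])
    truth = np.r_[np.zeros(300), np.ones(300)]
    nm = tn.fit_niche_model(emb, k=2, seed=0)
    labels = nm.classify(emb)
    assert adjusted_rand_score(truth, labels) == 1.0
    resp = nm.responsibilities(emb)
    np.testing.assert_allclose(resp.sum(axis=1), 1.0)


def test_gmm_k1_single_label():
    rng = np.random.default_rng(1)
    emb = rng.normal(size=(50, 3))
    nm = tn.fit_niche_model(emb, k=1, seed=0)
    assert set(nm.classify(emb)) == {"T1"}


def test_gmm_requires_k_rows():
    with pytest.raises(ValueError):
        tn.fit_niche_model(np.zeros((3, 2)), k=4)


def test_em_loglik_nondecreasing():
    from sklearn.mixture import GaussianMixture

    rng = np.random.default_rng(2)
    emb = np.vstack([rng.normal(0, 1, (200, 4)), rng.normal(4, 1, (200, 4))])
    gm = GaussianMixture(2, covariance_type="full", max_iter=1, warm_start=True,
                         random_state=0, tol=0, reg_covar=1e-6)
    lls = []
    for _ in range(15):
        gm.fit(emb)
        lls.append(gm.lower_bound_)
    assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))


# ---------------------------------------------------------------------------
# hexbin maps and cell assignment
# ---------------------------------------------------------------------------

def test_hexbin_min_count_and_majority():
    rng = np.random.default_rng(3)
    # 10 transcripts in one tight cluster (all T3), 9 in another far away
    xy = np.vstack([
        np.full((10, 2), 50.0) + rng.normal(0, 0.3, (10, 2)),
        np.full((9, 2), 500.0) + rng.normal(0, 0.3, (9, 2)),
    ])
    t = make_transcripts(xy[:, 0], xy[:, 1])
    labels = np.array(["T3"] * 10 + ["T1"] * 9)
    hmap = tn.hexbin_map(t, labels, bin_width=5.0, min_bin=10)
    assert len(hmap.labels) == 1
    assert hmap.labels[0] == "T3"


def test_hexbin_tie_breaks_to_lowest_label_index():
    xy = np.full((10, 2), 20.0)
    t = make_transcripts(xy[:, 0], xy[:, 1])
    labels = np.array(["T7"] * 5 + ["T2"] * 5)
    hmap = tn.hexbin_map(t, labels, bin_width=5.0, min_bin=10)
    assert hmap.labels[0] == "T2"


def test_hexbin_matches_point_in_polygon_oracle():
    """Bin assignment equals brute-force point-in-hexagon with shapely."""
    from shapely.geometry import Point, Polygon

    rng = np.random.default_rng(4)
    xy = rng.uniform(5, 95, size=(400, 2))
    t = make_transcripts(xy[:, 0], xy[:, 1])
    labels = np.array(["T1"] * 400)
    hmap = tn.hexbin_map(t, labels, bin_width=5.0, min_bin=1)
    R = 5.0 * 2 / 3
    hexes = []
    for (q, r), c in zip(hmap.axial, hmap.centers):
        ang = np.deg2rad(np.arange(0, 360, 60))  # flat-top corners
        hexes.append(Polygon(np.c_[c[0] + R * np.cos(ang), c[1] + R * np.sin(ang)]))
    counts = np.zeros(len(hexes), dtype=int)
    for p in xy:
        inside = [i for i, h in enumerate(hexes) if h.buffer(1e-9).contains(Point(p))]
        assert len(inside) >= 1
        counts[inside[0]] += 1
    assert counts.sum() == 400
    np.testing.assert_array_equal(np.sort(counts), np.sort(hmap.counts))


def test_cells_take_nearest_bin_label():
    t = make_transcripts(np.r_[np.full(10, 10.0), np.full(10, 110.0)],
                         np.r_[np.full(10, 10.0), np.full(10, 10.0)])
    labels = np.array(["T1"] * 10 + ["T2"] * 10)
    hmap = tn.hexbin_map(t, labels, bin_width=5.0, min_bin=10)
    cells = pd.DataFrame({
        "cell_id": ["a", "b", "c"],
        "x": [hmap.centers[0, 0], hmap.centers[1, 0], 0.0],
        "y": [hmap.centers[0, 1], hmap.centers[1, 1], 0.0],
    })
    out = tn.assign_cells_to_transcript_niches(cells, hmap)
    assert list(out["transcript_niche"][:2]) == list(hmap.labels[:2])
    assert out.iloc[2]["transcript_niche"] == hmap.labels[0]


def test_cell_assignment_matches_exhaustive_search():
    rng = np.random.default_rng(5)
    xy = rng.uniform(0, 100, size=(20000, 2))
    t = make_transcripts(xy[:, 0], xy[:, 1])
    labels = rng.choice(["T1", "T2", "T3"], size=20000)
    hmap = tn.hexbin_map(t, labels, bin_width=5.0, min_bin=10)
    assert len(hmap.centers) > 50
    cells = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(200)],
        "x": rng.uniform(0, 100, 200), "y": rng.uniform(0, 100, 200),
    })
    out = tn.assign_cells_to_transcript_niches(cells, hmap)
    cxy = cells[["x", "y"]].to_numpy()
    d = np.linalg.norm(cxy[:, None, :] - hmap.centers[None, :, :], axis=-1)
    expect = hmap.labels[d.argmin(axis=1)]
    assert np.array_equal(out["transcript_niche"].to_numpy(), expect)


def test_no_bins_flags_unassigned():
    hmap = tn.hexbin_map(make_transcripts([], []), np.array([]), 5.0, 10)
    cells = pd.DataFrame({"cell_id": ["a"], "x": [0.0], "y": [0.0]})
    out = tn.assign_cells_to_transcript_niches(cells, hmap)
    assert out.iloc[0]["transcript_niche"] == "unassigned"
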