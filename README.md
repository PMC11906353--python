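# fibroniche

Spatial-transcriptomics analysis of distal lung remodeling: niche discovery,
cell-type proximity statistics, differential abundance, lumen segmentation
and airspace pseudotime, built for imaging-based platforms (Xenium-style
per-transcript tables) and validated end to end on synthetic tissue with
planted ground truth.

**Who it is for.** Computational biologists analysing in-situ spatial
transcriptomics of fibrotic lung (or any tissue with lumen-like negative
space): the package takes per-transcript tables (µm coordinates, gene label,
decoding quality value QV, optional nucleus assignment) plus per-cell
metadata, and produces niche labels, proximity log odds ratios, differential
abundance/expression tables, segmented alveolar airspaces and
pseudotime-association test results.

## The methods at the core

* **Transcript niches (cell-segmentation-free).** Per sample, transcripts
  form a spatial graph (edges at Euclidean distance < d = 3.0 µm; components
  with < 10 nodes dropped). A two-hop mean-aggregation embedding
  (GraphSAGE-style; 20/10 sampled neighbors, 50 dimensions per hop, trained
  10 epochs by link prediction on positive/negative node pairs) maps each
  transcript to a vector summarizing its local gene milieu; a Gaussian
  mixture (k = 12 by default) over the embeddings defines niches T1..Tk.
  Hexagonal bins (width 5, ≥ 10 transcripts) take majority labels, and cells
  inherit their nearest bin's label.
* **Cell niches.** k-means (k = 12) over each cell's 25-nearest-neighbor
  cell-type composition, labels C1..Ck by decreasing size.
* **Proximity.** For ordered type pairs (A, B): is an A cell more likely than
  other cells to have a B neighbor within 60 µm? Logistic regression on the
  binarized outcome; log OR with 5–95% Wald CI and BH-FDR, overall and per
  niche.
* **Differential abundance.** Logit-transformed proportions (0.5
  pseudocount), per-feature linear models with empirical-Bayes variance
  moderation (moderated F across disease groups; moderated t against percent
  pathology), niche-representative gene contrasts, a per-cell-type
  contamination filter (≥ 5 counts-per-1K in ≥ 30% of cells), and voom-style
  weighted pseudobulk DE (log2 CPM, mean–variance lowess trend, TMA
  covariate).
* **Lumen segmentation.** Transcripts (excluding immune-cell transcripts)
  rasterized at 5 µm/pixel; dilation/erosion/closing produce a tissue mask;
  enclosed background components are lumens; the tissue boundary is an alpha
  shape. Cells within a wall-thickness cutoff join the nearest lumen; five
  compositional filters (25–500 cells, ≥ 5% epithelial, span ≥ 110 µm,
  endothelial C10/C12 < 0.3 and airway C1 < 0.2, maximum niche in
  {C2, C5, C8, C3, C11}) isolate alveolar airspaces.
* **Pseudotime + NB-GAM.** Airspaces ranked by descending healthy-niche
  transcript share (pseudotime = rank/N). Per feature,
  `log μ = s(t) [+ Σᵢ s(pᵢ)] + log n + U` with a negative-binomial response,
  cubic regression splines (5 quantile knots, sum-to-zero constraint,
  second-difference penalty, GCV), log-exposure offset and TMA covariate;
  association = Wald test on the s(t) coefficients with BH-FDR. Significant
  genes' predicted smooths (2,000 points, z-scored) are split into bimodal
  vs unimodal shapes and staged into homeostasis / early / intermediate /
  late remodeling by spectral clustering ordered by rolling-mean peak time.

See `docs/methods.md` for assumptions, parameter defaults and numerical
details.

## Worked example

```python
import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from fibroniche import (
    preprocess as pp, transcript_niche as tn,
    proximity as px, synthetic_data as sd, pseudotime_gam as pg,
)

# 1. synthetic lung core with planted truth (450x450 um, 2 lumens, 4 niche regions)
cfg = sd.SyntheticConfig(seed=7, tissue_width=450, tissue_height=450,
                         n_lumens=2, n_free_cells=800)
tx, cells, truth = sd.generate_tissue(cfg)

# 2. QC: drop low-quality transcripts and control probes
txf, report = pp.filter_transcripts(tx, return_report=True)

# 3. transcript niches: graph -> embedding -> GMM -> hexbin -> cells
g = tn.build_transcript_graph(txf, d=3.0)
model = tn.train_embedding([g], tn.EmbeddingConfig(epochs=10), seed=0)
emb = tn.embed_nodes(model, g)
niches = tn.fit_niche_model(emb, k=4, seed=0)
labels = niches.classify(emb)
hmap = tn.hexbin_map(txf.iloc[g.source_rows], labels)
assign = tn.assign_cells_to_transcript_niches(cells, hmap)
ari = adjusted_rand_score(truth.niche_label_cell, assign["transcript_niche"])

# 4. proximity: planted 4x attraction between types A and B
pcells = sd.generate_proximity_cells(2000, attraction=4.0, seed=1)
res = px.proximity_logit(px.find_neighbors(pcells, radius=60.0), pcells)

# 5. airspace pseudotime + NB-GAM association on 300 airspaces
pat = {f"g{i:04d}": "flat" for i in range(18)} | {"g0018": "early", "g0019": "early"}
counts, atruth = sd.generate_airspace_counts(300, 20, pat, seed=2, amplitude=2.0)
traj = pg.order_airspaces(shares=pd.Series(1 - atruth.trajectory_truth, index=counts.index))
fits = pg.fit_feature_gams(counts, traj, offset="rowsum", tma=atruth.tma)
assoc = pg.association_test(fits).set_index("feature")
```

Output (about two minutes on one CPU):

```
82,733 transcripts, 1,006 cells
retained 68,177 transcripts (removed 12,432 low-QV, 2,124 controls)
link-prediction accuracy 0.97, cell-level niche ARI vs planted regions 1.00
B-near-A log OR 1.22 (90% CI 0.96..1.48; planted log 4 = 1.39)
early-peak genes detected at FDR<0.05: 2/2; median null p 0.44
```

Reading the numbers: the embedding's held-out link-prediction accuracy (0.97)
says the model has learned local neighborhood structure; the cell-level
adjusted Rand index of 1.00 against the planted regions says the full
graph→embedding→mixture→hexbin chain recovered the tissue's niche layout
exactly. The proximity log odds ratio estimates how much more likely a
type-B cell is to sit within 60 µm of a type-A cell than other cells are —
its 90% interval covers the planted log 4. In the GAM block, both genes
planted with an early-remodeling expression bump are detected at FDR < 0.05
while the 18 flat genes yield null-like p-values (median 0.44).

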