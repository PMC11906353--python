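# Methods

`fibroniche` reimplements, as a tested Python pipeline, a spatial-
transcriptomics analysis of distal lung remodeling in pulmonary fibrosis:
niche discovery at transcript and cell resolution, cell-type proximity
statistics, proportion-based differential abundance, morphological lumen
segmentation, and airspace pseudotime with negative-binomial GAM association
tests. Every stage is exercised end to end on synthetic tissue with planted
ground truth. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic benchmarks do and do not show.

## Input model

The pipeline consumes Xenium-style per-transcript tables: one row per decoded
molecule with µm coordinates (`x_location`, `y_location`), a gene or
control-probe label, a decoding quality value (QV), an optional nucleus/cell
assignment and a sample label; plus per-cell metadata (centroid, nucleus
area, sample, disease group, percent pathology, TMA of origin). Analysis uses
only high-quality gene transcripts: rows with QV < 20 (strict) or from
control probes (blanks, negative-control probes/codewords, unassigned
codewords) are removed first. Cell-level expression counts **nuclear**
transcripts only; restricting to the nucleus limits the cross-cell spillover
("contamination") inherent to segmentation-free molecule assignment.

Cell QC keeps nuclei with ≥ 12 transcripts over ≥ 10 unique genes, each
control-probe class and their cumulative percentage ≤ 5% of the cell's
high-quality transcripts, and nucleus area within [6, 80]. The platform's
area column is treated as the unit source; the bounds are configuration
(`area_min`, `area_max`) because the unit convention (µm vs µm²) is
ambiguous in practice.

## Transcript niches

Niches are discovered without cell segmentation. Per sample, transcripts form
a spatial graph: nodes are retained transcripts carrying a one-hot gene
feature; edges join pairs at Euclidean distance strictly below `d` = 3.0 µm;
connected components with fewer than 10 nodes are dropped.

A two-hop neighborhood-aggregation (GraphSAGE-style) model embeds each node:

* hop 1: `h¹_v = ReLU(W_s¹ x_v + W_n¹ · mean{x_u : u ∈ N₁(v)} + b¹)`, 50-dim;
* hop 2: `z_v = W_s² h¹_v + W_n² · mean{h¹_u : u ∈ N₂(v)} + b²`, 50-dim,
  then L2-normalized.

The second hop is **linear**. This is a deliberate choice: with a ReLU on the
output the embeddings are confined to the non-negative orthant, which we
found makes the downstream Gaussian mixture merge distinct regions whose
embeddings land near the same corner; the linear output preserves signed
structure and the mixture then separates planted regions cleanly.

Training is unsupervised link prediction: positive pairs are graph edges,
negatives are uniform node pairs, scored by a calibrated dot product
`σ(a·z_u·z_v + c)` under binary cross-entropy, optimized with Adam. During
training, neighborhoods are subsampled (20 neighbors at hop 1, 10 at hop 2)
and the training graph is the union of per-sample subgraphs grown from 5,000
random root nodes and their three-hop neighborhoods. Ten epochs are the
default; positive pairs per epoch are capped (50,000) so training completes
in minutes on one CPU at the package's benchmark scale. A 5% edge holdout
gives the reported link-prediction accuracy. Inference uses **full**
(unsampled) mean aggregation via sparse matrix products, so identical
neighborhoods map to identical vectors, embeddings are deterministic given
the frozen weights, and new samples can be projected into an existing niche
space without retraining.

Niches are a full-covariance Gaussian mixture (default k = 12; k = number of
planted regions in benchmarks) over the embeddings, initialized by k-means++
with a fixed seed, five initializations, and a small diagonal ridge
(`reg_covar` = 1e-6). For very large node sets the mixture is fitted on a
50,000-row subsample and used to classify all nodes.

Spatial summaries use flat-top hexagonal bins whose horizontal pitch is the
bin width (default 5 µm); point-to-bin assignment is exact cube-coordinate
rounding. Bins with fewer than 10 transcripts are dropped; each bin takes the
majority niche label with ties broken toward the lowest niche index; bins are
ordered by axial coordinates so nearest-bin queries are reproducible. Cells
inherit the label of the nearest retained bin centroid.

## Cell niches

Each cell is described by the cell-type composition of its 25 nearest
neighbors (self excluded; neighbors never cross sample boundaries, since
samples are distinct tissue cores; distance ties resolve by cell order).
k-means (default k = 12) over the composition vectors defines niches C1..Ck,
labeled by decreasing cluster size so the naming is reproducible.

## Cell-type proximity

For each ordered pair (anchor type A, target type B), every cell is binarized
as proximal (≥ 1 type-B neighbor within 60 µm, within-sample) or not, and a
logistic regression with the is-type-A indicator estimates the log odds
ratio. With one binary covariate the MLE is the closed-form 2×2 log odds
ratio, which is what the implementation computes, with a Wald 5–95%
confidence interval, two-sided p-value, and BH-FDR across pairs within each
stratum (all cells, and optionally per niche with both anchor and neighbor
restricted to the stratum). Tables with an empty cell are flagged degenerate
and clamped with a Haldane–Anscombe 0.5 correction; anchors with < 2 cells
yield no estimate. "Proximal" means within-radius; a graph-degree reading of
"first-degree neighbors" (e.g. a Delaunay first ring) is a possible
alternative not implemented. Neighbor angles are computed and stored but not
used by the statistic.

## Differential abundance and expression

Composition analyses act on logit-transformed per-sample proportions; counts
get a 0.5 pseudocount before proportions so zeros stay finite. Per-feature
linear models (one-way group design for the disease-group test; a continuous
percent-pathology covariate for trend tests) are moderated by empirical
Bayes: feature variances get a scaled inverse-chi-square prior fitted by
moments of log s² (digamma/trigamma closed forms, Newton trigamma inverse),
and the posterior variance is the precision-weighted blend. The group test is
a moderated F; trends use moderated t. For niche-level features, a sample is
excluded from a niche's test when its share of that niche is below 5×10⁻⁴.
Niche-representative genes fit, per gene, a linear model of logit gene
proportions over (sample, niche) units with sample effects, contrasting each
niche against the average of the others, FDR within niche.

Contamination-aware DE first filters genes per cell type: counts are scaled
per cell to counts-per-1K and a gene is tested within a type only when ≥ 30%
of that type's cells show ≥ 5 scaled counts — spillover from adjacent cells
is too sparse to clear this within-type prevalence bar. Pseudobulk DE across
annotation instances converts counts to log2(CPM) with a 0.5 pseudocount,
excludes genes below log2(CPM) = 8 in ≥ 50% of units, fits a lowess trend of
√(residual SD) against mean log2 CPM (a single global trend; no sample
quality weights), converts fitted values to per-observation precision
weights (1/trend⁴), and fits weighted linear models (one-vs-rest annotation
indicator + TMA batch covariate) with moderated t statistics.

## Lumen segmentation

Transcript positions — excluding transcripts of immune-lineage cells, which
accumulate inside airspaces — are binarized onto a raster (default 5
µm/pixel). Dilation (1 px), erosion (1 px) and closing (4 px disc) produce a
solid tissue mask; the closing radius is the one parameter that matters and
should be of the order of half the largest inter-cell gap (20 µm at the
default resolution) while staying below the smallest lumen radius of
interest. Background components fully enclosed by tissue become lumens
(labels 1..L); components connected to the exterior are not holes and get no
label. The concave outer boundary is an alpha shape over occupied pixel
centers (Delaunay triangles kept when circumradius < 1/α, default α = 1/(4
pixels), union of triangles), implemented in-package on scipy/shapely.

Cells are assigned to the nearest lumen via a Euclidean distance transform
with index lookup; cells farther than the wall cutoff (default 10 µm — the
order of a normal alveolar wall's thickness; not a published number) from
every lumen pixel get identifier 0. Per-lumen metrics (member count,
epithelial fraction, maximum pairwise nucleus distance via convex hull,
cell-niche proportions, tied set of maximum niches) feed five conjunctive
alveolar filters: 25–500 cells, ≥ 5% epithelial cells, maximum pairwise
nucleus distance ≥ 110 µm, endothelial niche proportions C10 < 0.3 and C12 <
0.3 with airway C1 < 0.2, and a maximum-niche set intersecting
{C2, C5, C8, C3, C11}. Ties in the maximum niche pass if any tied niche is
allowed.

## Airspace pseudotime and NB-GAMs

Airspaces are ordered by the share of their nuclear transcripts assigned to
the healthy alveolar transcript niche: descending share gives ascending
pseudotime, taken as rank/N in (0, 1] (ties break by airspace id). Ranks
rather than raw proportions stabilize knot placement.

Feature counts per airspace (genes, cell types, niches) are modeled as

    log μ = s(t) [+ Σᵢ s(pᵢ)] + log n + U

with a negative-binomial response (var = μ + αμ²), a fixed log-exposure
offset n (total transcripts for gene models, total cells for cell-type
models), an optional TMA factor U, and optional composition smooths s(pᵢ)
over cell-type proportions that absorb contamination-driven trends. Each
smooth is a cubic B-spline with 5 knots at covariate quantiles under a
sum-to-zero constraint (so the intercept is identifiable) and a
second-difference penalty; a single smoothing parameter shared across
smooths is chosen by GCV on a log grid (10⁻²…10⁴, 7 points). Fitting is
penalized IRLS alternated with maximum-likelihood dispersion (bounded
log-scale search); degenerate or collinear composition smooths are dropped
with a log message, keeping s(t).

Association with pseudotime is a Wald test that all s(t) coefficients are
jointly zero, using the sandwich covariance of the penalized estimator
V = (X'WX + λS)⁻¹ X'WX (X'WX + λS)⁻¹, chi-square reference on rank(V_ss)
degrees of freedom, BH-FDR across features. Because the constant function
lies in the penalty's null space, the statistic is calibrated under the null
regardless of λ (verified by simulation: null p-values pass a KS uniformity
test over 500 features).

Eligibility rules before fitting: features need ≥ 3 counts in ≥ 10 airspaces
(cell types) or in ≥ 10% of airspaces (niches); the composition-adjusted
per-(cell type, gene) analysis tests cell types with > 3 cells in ≥ 80
airspaces, uses as composition covariates the ≤ 15 types with > 3 cells in
> 300 airspaces, and restricts genes to the overall significant set with ≥ 3
copies in ≥ 50% of testing airspaces.

Significant genes' predicted smooths (2,000 grid points, z-scored per gene)
are clustered hierarchically (Ward, k = 20); a cluster's mean profile is
declared bimodal by an explicit rule replacing by-eye inspection: ≥ 2 local
maxima above 0.5 z separated by a trough below 0. Unimodal genes are
clustered spectrally (k = 4) and the clusters labeled homeostasis / early /
intermediate / late remodeling by increasing mean peak time, where a gene's
peak time is the argmax of the rolling mean (window 100) of its smooth.
Because the bimodality rule is a deterministic surrogate for visual
inspection, exact gene-set concordance with a human split is not claimed.

## Synthetic data

The generator emulates the structure of an imaging-based run on a lung core,
not its biology. Defaults (a 700×700 µm core, 5 non-overlapping round lumens
of radius 40–70 µm with epithelial-lined walls, ~2,500 cells at ~15 µm
spacing, 80 transcripts per cell on average, 60% nuclear, 4 Voronoi niche
regions, 4 cell types × 4 markers, 5% contamination, 3% control probes, 15%
low-QV transcripts from a fail distribution below QV 20) give ~200k
transcripts and are the conditions under which the acceptance suite runs.
Key emulated features: spatial transcript clustering around planted nuclei
(uniform in a disc; nuclear draws in the nucleus disc), cell-type marker
profiles, niche regions with private gene vocabularies mixed 50/50 with type
profiles, spillover transcripts that keep their position but swap their
expression source to the nearest other cell, a QV mixture straddling 20, and
ring lumens with intraluminal immune cells.

Airspace-level counts for the GAM benchmarks are negative binomial around
pattern-class means: flat, or Gaussian bumps on the severity axis centered
at 0.08 / 0.35 / 0.62 / 0.90 (homeostatic < early < intermediate < late by
construction), with log-normal exposure. The proximity generator controls
exactly the binary within-60-µm odds of the attracted pair (the near-region
probability is the exact shapely area of the union of discs), so the planted
log odds ratio is log(attraction) with no geometric approximation.

What passing benchmarks do **not** show: robustness to real segmentation
errors, panel-specific expression overlap between cell types, batch effects
beyond a categorical TMA shift, anisotropic or non-circular lumens, or
biological coupling between niches, composition and severity. The synthetic
regions are convex and vocabulary-driven; real niches are weaker and
blurrier, so real-data ARIs will be lower than the benchmark's.

## Problem sizes and determinism

Benchmark sizes — ~200k transcripts for niche recovery, 1,000–2,000 cells per
proximity replicate (200 null replicates), 12 samples × 20 features × 100
replicates for composition power, 300 airspaces × 50 simulations for GAM
power — are the package's chosen desk-scale study conditions; all reported
quantities in `scripts/acceptance.py` are recomputed from scratch at run
time. Every stochastic step flows through `numpy.random.default_rng` seeds
derived from a single seed; generation, graph construction, training and
clustering are deterministic given that seed (training additionally depends
on the sampling order it seeds itself).
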