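# Methods

This note documents the models and procedures implemented in
`phenotil`, their assumptions, the defaults that matter, and the
numerical choices made where the design was genuinely open. It states
no empirical result beyond what the test suite and
`scripts/acceptance.py` compute.

## Contextual TIL features

Each TIL is described by its neighborhood at three scales. With
`dL = 20` px (the average lymphocyte diameter at 20×, 0.5 µm/px), the
radii are `dL·10 = 200`, `dL·20 = 400`, `dL·30 = 600` px. Discs are
**cumulative** (nested, closed at the boundary: distance ≤ r), not
annular: the wording "incremental increasing radii" reads most
naturally as nested discs, and cumulative counts give the monotonicity
invariant `n_total(r200) ≤ n_total(r400) ≤ n_total(r600)` that the
suite checks. The index cell is excluded from its own neighborhoods.

Per disc, 96 descriptors over the TIL and non-TIL neighbor groups:

| family | count | content |
|---|---|---|
| A density | 6 | n_TIL, n_nonTIL, n_total, TIL fraction, TIL/mm², nonTIL/mm² |
| B graph distance | 8 | centroid distance to {TIL, nonTIL} × {mean, std, min, max} |
| C neighbor morphology | 40 | {area, perimeter, eccentricity, equiv. diameter, solidity} × {mean, std, min, max} × class |
| D neighbor color | 18 | per-nucleus mean {R, G, B} × {mean, std, max} × class |
| E neighbor texture | 24 | 12 co-occurrence statistics × class (mean over neighbors) |

6 + 8 + 40 + 18 + 24 = 96 per radius; 3 radii give 288. This catalog
is a reconstruction: the published description fixes the families and
the 288 total but not the itemized list, so the partition above was
chosen to satisfy both constraints exactly and is frozen in
`feature_catalog()`.

Numerical conventions: distances are Euclidean in pixels; group
standard deviations are population (ddof = 0); an **empty neighbor
group contributes 0** to every statistic (including `frac_til` when
the disc is empty). The zero-fill is applied before any downstream
standardization and is monotone with "no signal" — it avoids NaN
propagation into the mixture model at the cost of conflating "no
neighbors" with "zero-valued neighbors", which the density family
disambiguates.

Haralick texture is computed per nucleus on the 8-bit grayscale
bounding-box patch, 32 gray levels, co-occurrence at distance 1
averaged over the 4 principal directions (symmetric GLCM). The 12
statistics are angular second moment, contrast, correlation,
sum-of-squares variance, inverse difference moment, sum average, sum
variance, sum entropy, entropy, difference variance, difference
entropy, and the first information measure of correlation. Degenerate
patches (constant, or too small to form a pixel pair) use the
constant-patch convention: ASM 1, correlation 1, entropies and
contrast 0.

## Niche clustering

TIL vectors are z-scored with statistics learned on the training TILs
(zero-variance features are retained, recorded, and given unit scale
so they stay inert); assignment always reuses the training
standardization, so re-assigning the training set reproduces training
labels. The mixture has K = 8 components — adopted as the published
configuration; a BIC sweep helper exists but is non-normative —
with **diagonal covariances and a variance floor of 1e-6**: a full
288×288 covariance per component is ill-conditioned at the cohort
sizes the package targets. EM uses k-means++ initialization with 5
seeded restarts (best log-likelihood kept), 200 iterations;
non-convergence is flagged, not fatal. Hard labels are the argmax
posterior responsibility, ties broken toward the lowest cluster index.
Fewer than 10·K TILs is an error.

## Survival risk model

OSRS is the exact linear combination `N @ β` on **raw counts** (the
score is described as a combination of cluster *numbers*); a
proportion mode (`use_proportions=True`) normalizes each row by the
patient's TIL total for burden-adjusted analyses. β comes from a Cox
proportional-hazards fit under an elastic-net penalty (mixing weight
0.5 by default; Efron tie handling). Penalty strength is selected
among a small grid (0.01, 0.1, 1.0 by default) by mean out-of-fold
log partial likelihood over seeded 5-fold splits — the grid is
deliberately coarse because the 8-dimensional problem is insensitive
to fine tuning. Zero-variance count columns are retained with β forced
to 0. Preconditions: n ≥ 30 patients, ≥ 10 events.

The dichotomization cutoff is the median training OSRS; **ties at the
cutoff go to "low"** (the published rule says "higher than the
median", leaving equality open; the choice is fixed and documented).
Cluster roles follow the sign of β (positive = constructive, negative
= obstructive, zero = neutral).

Evaluation: two-sided Mantel–Haenszel log-rank p; hazard ratio (with
95% CI) from a univariable Cox fit on the binary group; Harrell's C
over continuous scores with higher score = higher risk, ties in score
counting ½, and a Noether-type standard error √(C(1−C)/n_pairs);
Kaplan–Meier product-limit curves per group with at-risk counts.

## Comparator families

denTIL is 19 tile-level density features. Three are fixed by their
published description (TIL count / tissue area, TIL count / nuclei
count, TIL area / tissue area); the remaining 16 are a documented
completion (counts, areas in mm², their ratios with 0-guards, mean
nuclear areas, TILs per 1000 nuclei) — the full original list lives in
prior work and only its cardinality is normative here. Ratios with
zero denominators return 0 and flag the feature. spaTIL is explicitly
reduced (the full 350-item catalog belongs to prior work): TIL and
non-TIL clusters are connected components of the within-class centroid
graph at a linkage radius (default 50 px), summarized by cluster
counts, convex-hull area statistics, the fraction of TIL hulls
intersecting a non-TIL hull, and the mean cross-class hull-centroid
distance. Patient aggregation computes mean, median, skewness and
kurtosis (adjusted sample estimators; kurtosis is excess) per
tile-level feature; higher moments are 0-filled and flagged below 3
(skewness) or 4 (kurtosis) tiles.

## Stain normalization and segmentation

Macenko normalization estimates a tile's two stain vectors in optical
density space (background below OD 0.15 excluded; SVD plane of tissue
OD; stain directions at the 1st/99th percentile angles within the
plane, the first axis oriented into the OD cone so angles cannot wrap)
and remaps concentrations — rescaled by the 99th-percentile
concentration ratio — onto a reference profile (the standard H&E OD
basis by default). Concentrations are not clipped during
reconstruction, so remapping a pure two-stain tile onto its own
profile is lossless up to 8-bit quantization. Tiles with under 1%
tissue pixels raise an error.

Segmentation is a classical marker-controlled watershed: hematoxylin
channel by color deconvolution, Gaussian smoothing (σ = 1.5), Otsu
foreground threshold (with a guard rejecting blank tiles), Euclidean
distance transform, local-maximum markers (minimum separation 5 px,
matching the lymphocyte radius), watershed, and a 16 px² minimum
object area (sub-lymphocyte debris). Externally produced masks can be
ingested directly. TIL classification runs in rule mode (area ≤ 280
px², solidity ≥ 0.85, mean brightness ≤ 135 — small, compact, dark)
or as a linear maximum-margin classifier on the descriptor vector; rule
mode never leaves a cell unassigned.

## Registration and subtype pairing

The H&E↔IF transform is piecewise linear: Delaunay triangulation of
≥ 4 non-collinear source control points, one exact affine per
triangle. It is exact at control points and continuous across edges;
points outside the hull are extrapolated with the nearest triangle's
affine and flagged. `inverse()` inverts the per-triangle affines on
the mapped triangles (located by barycentric search); re-fitting with
swapped point roles agrees with it only when both triangulations share
the same simplices.

Subtype quantification isolates the membrane as a ring: the
(transformed) nucleus dilated by `ring_width` (default 2 px ≈ 1 µm at
20×, a declared default — the membrane geometry is not dimensioned in
the source description) minus the nucleus. Mean ring intensity per
marker is divided by the per-core AQUA scalar (an input; its
computation is out of scope) and the argmax marker is the label. Exact
ties are `unassigned` rather than resolved by a priority order, which
would bias a marker. Niche×subtype composition rows are percentages
over assigned cells, with unassigned counts reported separately and
raw contingency counts exported for chord diagrams.

## Gene association

Pearson correlation of each gene against the 8 niche counts and/or
OSRS; genes or targets with zero variance are flagged missing.
"Activation genes" per target are those with |r| above 50% of the
maximum |r| over genes — the maximum is taken in absolute value
(both positively and negatively correlated pathways are reported
downstream), with signs retained in the correlation matrix. Enrichment
is a one-sided hypergeometric over-representation test against
user-supplied GMT gene sets intersected with the expression universe,
with Benjamini–Hochberg FDR across sets; live ontology queries are
replaced by versioned GMT files for determinism.

## Synthetic data: what it emulates and what it does not

TIL centroids follow a Thomas cluster process (uniform hotspot
parents; Gaussian offspring, default 6 hotspots × Poisson(40) at
dispersion 60 px on a 2048 px tile) over a homogeneous Poisson
background of non-TILs (default 1000 /mm², a typical tumor-tile
nuclear density). Each hotspot draws a phenotype; offspring inherit
it, so phenotypes form spatial niches and the contextual features of
co-located TILs are correlated — the structure the clustering stage
needs. Per-cell descriptors are Gaussian in descriptor space with
structured per-phenotype offsets (area, eccentricity, color);
lymphocyte nuclei are ~14 px equivalent diameter, dark; non-TILs
larger and paler. Overlap is resolved by rejection sampling with
minimum centroid separation 0.8·(r₁+r₂) (configurable; raised to ≥ 1.2
for "well-separated" segmentation fixtures), 50 retries per cell, then
a degenerate-config error — the bound keeps the watershed stage
solvable by construction.

Survival times are exponential (memoryless, so closed-form sanity
checks hold) with log-hazard equal to the standardized `N @ β*`;
censoring is independent: a `censor_rate` fraction of patients is
censored at a uniform fraction of their event time, giving exact
control of the censoring fraction. The pipeline's cohort simulation
draws per-patient phenotype propensities from a Dirichlet(0.5) prior
so niche composition varies across patients; a rare hotspot-parent
draw that overpacks a tile triggers the generator's degenerate-config
error and the pipeline redraws that tile's seed (bounded retries,
deterministic under the stage seed). The default planted β* mirrors a
published adenocarcinoma coefficient pattern; sign-recovery
experiments use `STRONG_BETA_STAR` (the same signs at uniform
magnitude) because signs of near-zero coefficients carry no
recoverable signal. IF stacks paint the true subtype's channel on an
exact membrane ring at coordinates distorted by the same
piecewise-linear model the registration fits, so noise-free recovery
is exact by construction. Expression planting uses
`x = r·z + √(1−r²)·ε` against the standardized target-cluster count,
fixing the population correlation at `r`.

What passing tests therefore show: the implementation correctly
computes its declared quantities and recovers effects *of the planted
form*. What they do not show: robustness to real H&E variability
(stain spectra drawn from tissue chemistry, nuclear pleomorphism,
cutting artifacts, non-elliptical nuclei, tumor/stromal architecture),
to model misspecification of the survival linkage, or to imperfect
upstream segmentation feeding the feature stage.

## Problem sizes

Test and acceptance experiments use the sizes stated with the method:
sign-recovery and separation on 20 replicates of n = 300 cohorts with
~30 TILs per cluster; the K = 8 fit on 20,000 288-dimensional TIL
vectors; oracle equivalence on 20 random 200-cell maps; the end-to-end
pipeline demo on 50 patients × 3 tiles (smaller 384–512 px tiles in
the test suite, with densities scaled to tile area).

## Known limitations

- The 96-feature per-radius catalog and the 16-feature denTIL
  completion are reconstructions, exact only in family structure and
  cardinality.
- Diagonal mixture covariances cannot represent correlated feature
  noise within a niche; with strongly correlated features the
  component count and assignments should be interpreted cautiously.
- The C-index standard error is the Noether-type approximation, which
  ignores the correlation between pairs sharing a patient.
- Rule-mode TIL classification thresholds are tuned to the synthetic
  descriptor distributions; real tissue requires the classifier path
  trained on annotated nuclei.
- `quantify_subtype` materializes a full-frame mask per cell; it is
  sized for tiles/TMA cores, not whole-slide frames.
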