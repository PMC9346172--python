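# Methods

This note documents the models, conventions and design choices behind
`toporad`, in the spirit of the methods documentation of statsmodels or
msprime: what is computed, under which assumptions, and what the synthetic
validation does and does not demonstrate.

## Imaging model and preprocessing

Volumes are isotropic scalar grids (HU) with the axial direction on the
third array axis; all indices are 0-based.

* **Isotropic resampling** (default 0.98 mm): cubic-spline interpolation
  of intensities (`scipy.ndimage.map_coordinates`, order 3); only grid
  points inside the original extent are produced. Masks are resampled
  *shape-based*: a per-slice signed Euclidean distance field (negative
  inside, in mm) is stacked, linearly interpolated to the isotropic grid
  and re-thresholded at 0. This preserves binarity exactly and convex
  shapes stay connected; a sphere's volume is reproduced within 5% at
  sub-millimetre spacing.
* **Requantization**: a look-up table maps the HU window [hu_min, hu_max]
  linearly onto 256 gray levels, `clamp(round(255·(v−hu_min)/width))` with
  **round-half-up** (documented because it decides level boundaries). The
  default window is the lung range −1350..150 HU. Thresholds quoted in HU
  use the offset convention `level/255 × width` above the window floor.
* **Edge enhancement**: a Laplacian-of-Gaussian filter. Its scale is not
  fixed by any external constraint, so the default is σ = 1 voxel,
  truncate = 4σ, applied in 3D to the requantized volume (both exposed in
  config). Because the Betti-map stage requires 8-bit input, the response
  is re-windowed to 0..255 by min-max taken inside the GTV bounding box
  dilated by 4 voxels — windowing over the whole field would let the lung
  background dominate and compress tumor contrast.
* **Slice selection**: the axial slice with the greatest in-mask pixel
  count; ties break to the smallest index.

## Betti-number maps

For threshold t the slice is binarized inclusively (pixel ≥ t → 1); the
inverted image is the exact logical complement (the two conventions
conserve pixel count, which fixes the ambiguity of strict vs non-strict
inequalities at equality). Per K×K window (K odd, default 9) anchored on a
stride-S lattice (default 3) from the slice origin, with windows fully
inside the slice (no padding, avoiding edge-artifact components):

* **B0** = number of 8-connected components of ones;
* **B1** = number of 4-connected zero components not touching the window
  border (the hole definition consistent with the 8/4 connectivity
  pairing);
* **B1/B0** ratio, defined 0 where B0 = 0. The ratio map is required to
  make the inverted-feature bookkeeping come out at 82 998 columns
  (54 × (2 polarities × 3 map types × 256 thresholds) + 54 slice
  features).

Implementation: all windows of one threshold are tiled onto a single
canvas with a one-pixel separator (background for B0, foreground for B1)
and labelled once; because a 1-pixel separator blocks both 8- and
4-adjacency across tiles, per-window counts equal brute-force per-window
labelling (property-tested against flood-fill oracles). This makes the
full 256-threshold, two-polarity stack of a 64² slice a ~1 s computation.

The characteristic asymmetry of the two polarities — a cavity wider than
the kernel is invisible to the original B1 map (the hole never fits inside
a window) but still counted by the inverted B0 map — holds by construction
and is asserted on phantom slices.

## Feature catalogue

Each derived image contributes exactly 54 features: 10 histogram
statistics (Mean, Variance, Skewness, Kurtosis, Energy = Σv², Entropy,
MeanAbsoluteDeviation, Median, Min, Max) and 44 texture features (22 GLCM,
11 GLRLM, 11 GLSZM). The exact composition of the 44 is a reconstruction —
only the per-image total of 54 is externally pinned (486 wavelet columns /
9 images) — and the catalogue is swappable.

Conventions, chosen once and property-tested against brute-force tallies:

* in-ROI min-max quantization to 32 gray levels before texture analysis
  (BN maps are quantized the same way on their own value range);
* GLCM: symmetric, distance 1, co-occurrence matrices of all directions
  (4 in 2D, 13 in 3D) summed before normalization;
* GLRLM: runs from all directions merged into one matrix; run percentage
  divides by ROI voxels × directions;
* GLSZM: fully-connected (8/26) equal-level zones, one matrix;
* histogram entropy is the Shannon entropy (base 2) of the empirical
  distribution of distinct values; degenerate 0/0 moments (constant ROI)
  are defined as 0.

Wavelet features use a one-level 3D separable coif1 decomposition with
periodization boundaries (the filter bank is then orthogonal; subband
energies sum to the input energy, which the tests assert). Subbands are
nearest-neighbor upsampled and cropped back to the input shape so the GTV
mask applies directly; order LLL, HLL, LHL, LLH, HHL, HLH, LHH, HHH per
spatial axis.

Feature names encode provenance, `Family_Name_Source[_thT]` (e.g.
`Histogram_Energy_iB0_th235`), and parse back to their components.
Map-derived features are computed over map pixels whose kernel *center*
lies inside the GTV mask, confining statistics to tumor.

## Cohort handling

* **Split**: patients are stratified jointly on the (LRR, DM) event
  indicators with largest-remainder allocation; candidate splits are
  redrawn (cap 100, then an error rather than silent acceptance) until
  two-sided Mann–Whitney U tests on both endpoints' time distributions
  give p > 0.05.
* **Normalization**: z-scoring with reference (training) mean and
  population SD; zero-variance columns are flagged and mapped to 0.
  Normalization precedes augmentation.
* **SMOTE for censored data**: there is no canonical adaptation of SMOTE
  to censored survival outcomes, so the package defines one and exposes
  it as a strategy: synthesis is stratified by event class; a synthetic
  patient is x + u·(x_nn − x) with u ~ U(0,1) and x_nn one of the k = 5
  nearest same-class neighbors, its time interpolates the parents' times
  with the *same* u, and its event flag is the class label. Exactly
  (factor − 1)·n_c synthetics per class keep event proportions unchanged;
  originals are retained verbatim. Default factor 4 (65 → 260 at the
  reference cohort size).

## Signature optimization

Per hyperparameter grid point (window R, kernel K, stride S) and blending
parameter α: normalize → augment → random half/half split into training
and validation subdatasets (stratified by event so both halves contain
events). Cox-net (elastic-net-penalized Cox partial likelihood, 50-point
geometric λ path, λ_min/λ_max = 0.01) ranks features by the number of path
points with a nonzero coefficient; ties break by the maximum |coefficient|
over the path, then column order. Every non-empty subset of the top ≤ 7
features is refit with an unpenalized Cox model (Efron ties); rank-deficient
or non-converging subsets are skipped and logged, never silently returned.
Radiomics scores are the linear predictor; both subdatasets are stratified
at the *training-subdataset* median and their nLPCs computed. Validation
always reuses training coefficients and median (no refitting leak;
asserted structurally in tests).

The **robustness index** combining the two nLPCs is defined here as their
harmonic mean 2TV/(T+V) (0 when both are 0): it rewards jointly high and
similar values and vanishes whenever the training nLPC does not generalize
at all. `min` and arithmetic-mean strategies are available behind the same
interface. The grid point/α/subset with maximal RI wins; the exhaustive
ledger of all evaluated combinations is retained.

Combined families (BWF, iBWF) concatenate the BF (resp. iBF) table at its
endpoint-optimal (R̂, K̂, Ŝ) with the WF table at its endpoint-optimal
window, then re-optimize only α and the subset.

For test-set evaluation the final model keeps the winning coefficients and
stratifies at the median score of the original (un-augmented) normalized
training cohort; the test set never uses its own median.

## Evaluation

Kaplan–Meier product-limit curves per risk group; two-sided two-group
log-rank test (χ², 1 df; p = 1 with a warning when no events exist in
either group); Harrell's c-index of the response −score with half credit
for response ties; nLPC = (−log₁₀ p) × c. Scores strictly above the
reference median are high risk (ties go low — the tie rule is a
convention and is documented rather than load-bearing). No
multiple-testing correction is applied across feature families; reports
say so.

## Synthetic cohort: what it emulates and what it does not

Phantoms are spheres (solid core, ground-glass-like rim of 1–3 mm,
lung background −800 HU, additive Gaussian noise of 20 HU) with 0–4
non-overlapping spherical cavities of constant intensity — geometry chosen
so B0/B1 ground truth is computable by construction. Cavity centers lie in
a narrow axial band (half-width 1 mm) about the equatorial plane, so every
planted cavity intersects the maximum-GTV slice that the 2D topological
analysis actually sees; isotropic placement is available
(`cavity_band_mm=None`) but decouples the planted count from the analyzed
slice. Survival times follow a Weibull proportional-hazards model with
inverse-transform sampling — the simplest model whose planted log-hazard
coefficients a Cox fit can recover. The default two-endpoint cohort
mimics the reference scale: 125 patients, administrative censoring at 162
months, observed times floored at 3 months, and baseline scales chosen so
the marginal event fractions land near 27% (LRR) and 18% (DM) under the
default covariate distribution.

Passing tests therefore demonstrate internal correctness and end-to-end
recoverability of a planted topological signal — not clinical validity:
phantoms lack anatomy, motion, scanner effects, lesion-shape diversity and
correlated clinical covariates, and the planted hazard is exactly
proportional.

## Problem sizes and numerical choices

The test suite runs at desk scale by design: 32³–48³ phantom grids,
cohorts of 40–200 patients, threshold subsampling (every 32nd level) and a
reduced hyperparameter grid for the recovery study (K = 5, S = 3,
α = 0.5, ten seeds at n = 200 with a cavity-count log-hazard of 0.8); the
full 256-threshold, 82 998-column extraction is exercised on one 64²
slice. Kernel anchoring, inclusive binarization, round-half-up
requantization, the 0-for-0/0 conventions and the ≤-median tie rule are
all fixed and documented above; determinism is guaranteed by seeding every
random source (cohort generation, splitting, SMOTE, subdataset split) and
by sorted-key serialization of all outputs.

## Known limitations

* Topology is 2D on a single axial slice; 3D Betti numbers/persistent
  homology are out of scope.
* The 44-texture-feature composition is a reconstruction (see above).
* The robustness-index formula and the censored-SMOTE time/event
  assignment are package-defined strategies, not externally fixed.
* Cox-net selection frequency is path-frequency, not bootstrap frequency
  (the alternative is pluggable).
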