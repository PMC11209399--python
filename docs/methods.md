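# Methods

This note documents the models, estimator conventions, numeric defaults
and design choices behind `nucmorph`, and what the synthetic fixtures do
and do not establish about real histology data.

## The measurement model

A tumor ROI is a raster at a known scan resolution (default 0.25 µm/px;
an ROI of 0.1185 mm², i.e. 0.5 high-power field at 4:3, is then a
1590×1192 px canvas). Nuclei are segmented to a binary foreground mask,
split into instances by connected-component labeling (8-connectivity by
default; configurable), converted to µm² via `pixels × resolution²`, and
objects with area **strictly below 7 µm²** are discarded as noise — the
boundary case of exactly 7 µm² is retained, because the removal rule is a
strict inequality. Border-touching instances are retained in the
algorithmic pathway (a flag can exclude them); margin exclusion is part
of the *manual* protocol only, where a human annotator cannot judge a
truncated nucleus.

Per-instance descriptors:

- **area** (µm²) — pixel count × resolution².
- **eccentricity** — from the ellipse matching the pixel set's second
  central moments: `√(1 − λ₂/λ₁)` with λ₁ ≥ λ₂ the covariance
  eigenvalues; 0 is a circle. A single-pixel instance is defined as 0; a
  collinear pixel set is capped just below 1.
- **solidity** — pixel count over the pixel count of the rasterized
  convex hull (hull on pixel centers). Measuring the hull in rasterized
  pixels rather than polygon area makes the solidity of a convex
  rasterized shape exactly 1, so "no indentations" reads as exactly 1.0.

The per-ROI profile aggregates each descriptor with mean, median, SD and
skewness; for area additionally the mean and median of the largest 10 %,
the 90th percentile, and the percentage of nuclei above two karyomegaly
thresholds. The default thresholds, 42.3 µm² and 50.5 µm², are the 90th
percentile and twice the median of a pooled reference annotation set;
`derive_karyomegaly_thresholds` recomputes both from any reference area
distribution. Because larger solidity means a *more regular* contour, the
profile also carries 1 − mean and 1 − median solidity so that, like every
other parameter, larger values read as more abnormal.

Estimator conventions (the source protocol names none of these, so the
package fixes mainstream defaults and states them):

- SD uses the sample (n−1) denominator; with fewer than 2 instances it is
  NaN ("undefined"), not an error.
- Skewness is the adjusted Fisher–Pearson standardized third moment
  (`scipy.stats.skew(bias=False)`); NaN below 3 instances.
- "Largest 10 %" is the ⌈0.1·n⌉ largest instances, so it is defined for
  every n ≥ 1 and the subset mean can never fall below the overall mean.
- Percentiles interpolate linearly between order statistics.

## Segmentation

The segmentation stage is deliberately an *interface*: downstream code
accepts any foreground mask or probability map, whether from the built-in
classical segmenter, a trained model, or imported files. The reference
segmenter is deterministic and dependency-light: grayscale transform →
Gaussian smoothing (σ = 1 px) → global threshold by between-class
variance maximization (Otsu) → filling of holes below 64 px. Foreground
is the dark side (hematoxylin-stained nuclei); a polarity flag handles
inverted contrast. A constant image yields an empty mask rather than an
error. Idempotence (re-segmenting the mask rendered back to two gray
levels reproduces the mask) holds exactly for the unsmoothed transform;
the blur kernel is the only boundary-moving step.

Two training-side primitives are provided framework-free (plain numpy),
so any backend's objective can be validated against them:

- **border weight map** `w(p) = w_c(p) + w0·exp(−(d1+d2)²/(2σ²))`, d1/d2
  the distances to the nearest and second-nearest instance. It equals the
  class weight far from nuclei and peaks in thin inter-nuclear gaps,
  pushing a learner to separate touching instances. Defaults w0 = 10,
  σ = 5 px, class weights (1, 1): the amplitude/length-scale of the
  classic separation map, chosen here as explicit package defaults.
- **weighted focal loss** `mean(w · α_t · (1−p_t)^γ · (−log p_t))` with
  γ = 2, α = 0.25 — the standard focusing constants. Saturated
  wrong-class probabilities are clamped at 1e−7 and logged. The loss is
  monotone: raising the probability of the true class at any pixel never
  increases it.

No trainable backend ships with the package; the classical segmenter
plus the backend protocol cover the pipeline's needs at desk scale.

## The manual protocol

The manual-morphometry subsample walks a 5×6 grid (30 equal cells whose
integer pixel edges tile the ROI exactly) in a meandering order — row 1
left→right, row 2 right→left, and so on from the upper-left corner —
annotating every nucleus of each visited cell, and stops at the first
cell boundary where ≥ 100 nuclei have been annotated (the current cell is
always completed, so subset sizes land just above the floor, a 101–137
style band on dense ROIs). Margin-cut nuclei are excluded. A nucleus
straddling interior grid lines is counted once, in the earliest visited
cell containing any of its pixels — this mimics "annotate it whole from
the cell where you met it" without double counting. The exact meander
geometry and the straddle tie-break are package choices (the protocol
description leaves both open); both are deterministic and configurable.

## Accuracy evaluation

- **Dice** on pixels, defined as 1 when both masks are empty.
- **Object matching**: the match rule is the critical under-specified
  detail of detection scoring; the package defaults to the community
  standard — greedy one-to-one assignment by descending IoU, a pair
  eligible at IoU ≥ 0.5 — with a pluggable alternative criterion
  (ground-truth centroid inside the predicted object). Precision =
  matches/n_pred, recall = matches/n_gt. Greedy matching is never better
  than the optimal assignment; tests verify it never exceeds a
  brute-force optimum on small instances.
- **RMSE / RMSE-to-range**: parameter error across cases, scaled by the
  spread (max − min) of the *ground-truth* values of the evaluated set —
  "how large is the error relative to the biological variation present".

## Prognostic statistics

**Horizon rules** (250-day default): tumor deaths within the horizon are
events; tumor-unrelated deaths within the horizon are censored at death;
lost-to-follow-up cases are excluded; everyone else is censored at the
horizon. The derived binary endpoint (ROC label) is tumor death within
the horizon vs survival past it; horizon-censored other-cause deaths
belong to neither class and are dropped from the binary set only.
Records last seen alive before the horizon carry the same information as
lost-to-follow-up and are excluded with a warning.

- **AUC** is the tie-corrected rank-sum probability
  P(score⁺ > score⁻) + ½P(=). The 95 % CI uses the asymptotic rank-based
  (DeLong) variance by default, with a stratified percentile bootstrap as
  the alternative (and as automatic fallback when the DeLong variance is
  degenerate); the orientation flag (`higher_is_worse`) defaults to
  larger-morphometry-equals-worse-prognosis.
- **Threshold selection** anchors sensitivity: among candidate
  thresholds (midpoints of adjacent distinct scores plus ±∞, positive
  call at score ≥ threshold) keep those with Sen ≥ 70 %; among them take
  the minimal sensitivity, then the maximal specificity, then the larger
  threshold. Anchoring all tests at one sensitivity makes their
  specificities directly comparable. With 10 positives the anchor is
  "exactly 7 of 10 mortality cases classified correctly" whenever a
  threshold realizes it.
- **`precision_from_rates`** reconstructs precision from *printed*
  Sen/Sp percentages: published rates are rounded from integer confusion
  cells, so with known class sizes TP = round(sen·n_pos) and
  FP = round((1−sp)·n_neg) recover the cells and the precision exactly.
- **Cox regression** is fit by lifelines with the Efron tie
  approximation — the default of mainstream survival software and
  accurate under the heavy ties a fixed horizon creates — with Wald 95 %
  CIs. A monotone partial likelihood (complete separation) is detected
  by a diverging coefficient/standard error and reported as
  non-estimable instead of a spurious number.
- **Kaplan–Meier / log-rank** via lifelines (product-limit curves;
  observed-vs-expected chi-square, k−1 df).
- **Agreement**: Cohen's kappa `(p_o − p_e)/(1 − p_e)` with chance
  agreement from the marginals; Light's kappa is the unweighted mean
  over all rater pairs. The verbal bins (slight/fair/…/almost perfect)
  are applied after rounding to 2 decimals, which is the only reading
  under which a kappa of 0.204 is labeled "slight" against a 0.21 bin
  edge.

## Synthetic fixtures: what they are and are not

The image generator draws nuclei as ellipses (log-normal area law,
default mean 30 µm², SD 10 µm²; uniform axis ratio in [1.1, 2.2]) whose
boundaries are perturbed by a low-order radial Fourier series (harmonics
2–5) with RMS amplitude `irregularity × mean radius`, rescaled so the
polygon area matches the sampled area exactly — irregularity therefore
changes solidity and local contour without biasing the area law, and
area/eccentricity/solidity are independently controllable. Placement is
rejection-sampled; with `overlap_fraction = 0` every instance is
separated by at least one background pixel in the full 8-neighbourhood,
so instances survive 8-connectivity relabeling as distinct components,
and the label mask is produced by rasterizing the stored boundary
polygons, making mask/polygon consistency exact by construction. A
chosen fraction of placements may skip the disjointness check; where
instances overlap the later label wins, emulating undersegmentation
risk. Rendering is contrast-only — dark nuclei on a pale background with
Gaussian channel noise (default SD 8 gray levels) — with no chromatin
texture, no stromal or inflammatory cells, and no staining artifacts.
Default geometry: 1590×1192 px at 0.25 µm/px with 630 nuclei per ROI
(the per-ROI annotation density of the motivating dataset); tests and
the acceptance script use proportionally smaller canvases (e.g. 760×570
with 150 nuclei) as the package's test-scale operating point.

Consequently, passing segmentation tests show the *pipeline around the
segmenter* is correct and that the classical segmenter handles
high-contrast, well-separated nuclei (Dice ≈ 0.999, detection F1 ≈ 0.99
on fixtures); they say nothing about performance on real H&E tissue,
where published Dice for this task is ~0.78–0.81 — real chromatin
texture, touching nuclei in thick sections, and non-neoplastic cells are
exactly what the fixtures omit.

The cohort generator plants exponential event times with rate
`λ₀·exp(Σβx)` (default λ₀ = 1/400 days), uniform administrative
censoring and a 250-day follow-up cap, so the true hazard structure is
known: Cox recovery of a planted log-HR = ln 3 at n = 2000 lands in
[2.5, 3.6], and the null 95 % CI covers HR = 1 in 92–95 % of 200
replicates at n = 100 under the default (heavily censored) conditions.
The rating generator gives each rater a noisy copy of a latent score and
personal cutpoints — enough to realize both agreement limits (identical
raters → κ = 1; case-independent calls → |κ| < 0.05 at n = 10⁴) and
heterogeneous rater behaviour, but not real pathologist psychology.

## Numerical and degenerate-input choices

- Every generator is a pure function of its spec; the seed is a spec
  field, and all randomness flows through one `numpy` Generator per call.
- Placement failures after 100 retries per nucleus reduce the instance
  count and are reported by a warning, never silently.
- Empty masks, blank images, all-censored cohorts, single-instance
  weight maps, and sub-minimum annotation sets all take defined warning
  paths rather than raising.
- Thresholds in `select_threshold` are midpoints of adjacent distinct
  scores, so results are invariant to monotone re-spacing of tied data.
- The acceptance script derives all sub-seeds from one `SeedSequence`
  (every derived seed < 2³¹).

## Known limitations

- The classical segmenter is a high-contrast method; it will not match a
  trained model on real stained tissue and is not meant to.
- No watershed-style splitting of merged instances is attempted (an
  experiment hook exists in the matching criterion, not the pipeline);
  undersegmentation of overlapping nuclei propagates into the area tail
  exactly as it does in practice.
- RMSE-to-range depends on the evaluated set's ground-truth spread;
  comparing ratios across sets with different spreads is not meaningful.
- Light's kappa inherits Cohen's kappa's sensitivity to skewed marginals;
  the interpretation bins are conventional, not inferential.
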