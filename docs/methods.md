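# Methods

`wheatspad` estimates winter-wheat canopy SPAD (a dimensionless
chlorophyll-meter reading) from plot-scale UAV multispectral imagery.
This note documents the models, conventions and numerical choices, and
what the synthetic data generator does and does not emulate.

## Pipeline overview

1. **Radiometric calibration.** Sensor digital numbers (DN) are mapped
   to surface reflectance with the empirical line method: one ordinary
   least-squares line per band fitted on the mean DN of ground panels of
   known reflectance (5/10/20/40 %). Panels are summarized by their mean
   DN (median available by config). Reflectance outside [0, 1.2] is
   masked and counted; values slightly above 1 are tolerated because
   specular pixels occur in field imagery.
2. **Plot extraction.** Plot polygons are rasterized with the
   pixel-center rule (a pixel belongs to the plot iff its center, at
   half-integer offsets from the affine origin, lies inside the
   polygon). Band order is authoritative from the container metadata,
   never from file page order.
3. **Spectral features (SF).** Five band means plus 25 vegetation
   indices, 30 features per plot in five classes: original bands (5),
   visible-only (7), red-edge-without-NIR (5), NIR-without-red-edge (8)
   and NIR+red-edge (5). Indices are evaluated on plot-mean reflectance
   (mean-then-index); an index-then-mean switch exists for sensitivity
   checks. Zero denominators yield NaN, never ±inf; tables are
   median-imputed before selection. `DCabCxc` "R/G\*3\*RE" is read
   left-to-right as (R/G)·3·RE and `ExB` "1.4\*B-G" as 1.4·B − G. One
   inherited quirk is kept verbatim: the mSR formula (NIR−B)/(RE−B)
   references the red-edge band although it is conventionally listed in
   the NIR-without-red-edge class.
4. **Texture features (TF).** Per band, plot pixels are min–max
   quantized to 64 gray levels (per plot, making texture robust to
   plot-level illumination; a fixed global range is available by
   config). A symmetric, normalized gray-level co-occurrence matrix is
   built in a 3×3 window at the 45° offset (pixel (r, c) paired with
   (r−1, c+1) in image coordinates, i.e. up-right). Eight metrics are
   evaluated per window — mean, variance, homogeneity, contrast,
   dissimilarity, entropy, second moment, correlation — and each metric
   map is summarized per plot by MAX, MIN, MEAN and SD (population SD):
   5 × 8 × 4 = 160 features. Windows straddling the plot mask are
   skipped, not padded (padding would invent texture at borders).
   Entropy uses 0·log 0 := 0 with natural log (base configurable);
   correlation of a zero-variance window is defined as 1, the common
   library convention. The windowed implementation is vectorized but
   agrees with naive pair counting to better than 1e-10 (tested).
5. **Feature selection.** *Boruta*: every candidate column gets a
   permuted shadow copy (at least five shadows are kept even when few
   candidates remain); a random forest is fitted; per-tree impurity
   importances become Z-scores (mean/SD across trees); a feature scores
   a hit when its Z-score beats the best shadow. A two-sided binomial
   test on hit counts, Bonferroni-adjusted across features, promotes to
   Confirmed or demotes to Rejected; undecided features stay Tentative
   (no rough-fix pass, because Confirmed (C-) and Confirmed+Tentative
   (CT-) are analysed as distinct model inputs). *RFE*: random-forest
   ranking, dropping the lowest-ranked `step` features per round; every
   visited subset size is scored by K-fold cross-validated RMSE and the
   CV-optimal prefix of the elimination path is returned (R-), ties
   toward the smaller subset. The selection forests use
   `max_features="sqrt"`; tree rankings are used rather than re-tuning
   the SVR at every elimination step.
6. **Fusion.** Column concatenation: the full SFTF table (190 columns),
   selection applied to SFTF (R-/C-/CT-SFTF), and the 3×3 pairwise
   fusions of {C-, CT-, R-}SF × {C-, CT-, R-}TF. Name clashes are
   disambiguated by feature-type prefix. Empty subsets skip their
   fusions with a log entry.
7. **SVR modelling.** Per stage, one random 2/3–1/3
   calibration/validation split (floor(2n/3); 24/12 at 36 plots) shared
   by every feature set so within-stage comparisons are paired. Features
   are standardized with statistics fitted on the calibration set only.
   An RBF-kernel SVR is tuned by inner K-fold grid search on the
   calibration set: C ∈ {0.1, 1, 10, 100}, γ ∈ scale-heuristic ×
   {0.1, 1, 10}, ε ∈ {0.01, 0.1, 1}; ties break toward smaller C, then
   larger ε (simpler models). Accuracy: R² in the conventional residual
   form 1 − Σ(y−ŷ)²/Σ(y−ȳ)², RMSE in SPAD units, and RPD =
   SD_reference / RMSE with SD_reference the calibration-set *sample*
   SD (n−1) by default — the convention consistent with the published
   descriptive tables this pipeline mirrors (validation-set SD is a
   config switch). The three study factorials enumerate 24 runs
   (SF/TF × full/C-/CT-/R- × 3 stages), 12 runs (SFTF variants) and 30
   runs (9 fusions + SFTF control per stage).

## Synthetic campaign generator

The field data behind the analysis are not public, so the generator
reproduces the *statistical structure* the method assumes:

* **Design.** 3 varieties × 4 nitrogen rates (0/100/200/300 kg ha⁻¹) ×
  3 replicates = 36 plots of 2 m × 8 m, rows at 0.30 m, observed at
  heading, flowering and late filling.
* **SPAD model.** mean SPAD = stage baseline + stage amplitude ·
  N/(N + K) + variety offset + Gaussian plot noise, truncated to the
  meter range [0, 60]; parameters that put the deterministic mean
  outside the range are rejected. Defaults (baseline/amplitude/K/SD):
  heading 35/17/100/3, flowering 37/17/100/3, late filling 6/42/150/3;
  variety offsets are 0 (no variety effect is emulated — none is
  reported, and no magnitudes exist to copy). These reproduce the
  published stage envelopes approximately (heading ≈ 30–55, late
  filling ≈ 6–44 with SD ≈ 11–12) and the stage ordering flowering >
  heading ≫ late filling.
* **Imagery.** Per-band canopy reflectance follows a logistic curve in
  SPAD (midpoint 25, scale 10): blue/green/red decline with SPAD, NIR
  rises (0.25 → 0.46), red edge sits in between and moves little. No
  radiative-transfer model is claimed — only monotone directionality is
  asserted and tested. Pixels mix canopy and soil through a
  raised-cosine row profile v = clip(cover + a·cos(2πx/period), 0, 1);
  stage cover is 0.85/0.90/0.65 (senescence opens the canopy at late
  filling) with per-plot jitter (SD 0.03/0.03/0.08). The stripe
  amplitude a rises logistically with *true* SPAD (0.05 → 0.30):
  vigorous canopies cast stronger row structure. Crucially, canopy
  *colour* responds to an "optical" SPAD = true SPAD + senescence noise
  (SD 1.5/1.5/7): late in the season leaves yellow at plot-specific
  rates, which decouples reflectance from the meter reading — the
  spectral-saturation/mixing problem that motivates texture fusion.
  Because structure tracks true SPAD while colour does not, texture
  carries complementary information exactly where the spectral signal
  degrades. Multiplicative lognormal speckle (σ 0.05/0.05/0.08) and a
  per-plot illumination factor (σ 0.03/0.03/0.06) complete the noise
  model. DN = (reflectance − offset)/gain per band with known
  coefficients; four grey panels carry exact nominal reflectances.
  All draws come from one explicitly passed seeded generator;
  identical (config, seed) reproduce bit-identical output.
* **Resolution.** The default ground sample distance is 0.05 m/pixel
  (plot = 40 × 160 px). Plot-level statistics are robust to resolution
  here because the stripe period (6 px) is well above the 3×3 GLCM
  window, and this size keeps the full three-stage factorial and the
  20-seed Monte-Carlo studies at desk scale; finer GSD is a config
  field.
* **What is not emulated:** orthomosaicking/stitching artifacts, BRDF
  and sun-angle effects, wheat spikes as a separate scattering layer,
  spatial autocorrelation between neighbouring plots, weather
  variation between flight dates. Passing tests therefore demonstrate
  that the pipeline recovers structure *of this kind*, not field-data
  accuracy.

## Monte-Carlo studies and problem sizes

* *Boruta sanity*: a planted copy of y among 20 noise columns must be
  Confirmed (20 seeds, n = 36); an all-noise table (30 columns,
  50 seeds) must keep the per-feature false-confirmation rate within
  the nominal binomial level. Note a small-sample subtlety: with
  n = 36, roughly one all-noise dataset in ten contains a noise column
  whose in-sample correlation with y is strong enough to beat the
  shadows genuinely and repeatedly — this is a property of the data,
  not a test-calibration failure; the per-feature rate stays well
  under the level (measured ≈ 0.003 at level 0.01).
* *Selection + fusion tendency*: 20 independent campaigns; each stage's
  SF and TF tables get 20 appended pure-noise columns each; Boruta
  (25 iterations, 40 trees), RFE (step 2 on SF, step 8 on TF,
  3-fold scoring, 25 trees) produce the C-/CT-/R- subsets; the nine
  fusions plus the unselected SF and TF tables are fitted with the
  full SVR grid on a shared split. Reported: per-stage medians of
  validation R² and the gain of the best dual-strategy model over the
  better single-type model. These reduced forest/step/fold sizes are
  runtime choices for the Monte-Carlo loop; the package-level defaults
  (100 trees, step 1, 5 folds, 100 iterations) remain the reference
  configuration, and generator statistics are identical in both.

## Degenerate inputs and tie-breaks

* Constant quantization input → all pixels level 0; constant GLCM
  window → contrast/dissimilarity/entropy 0, homogeneity/second
  moment 1, correlation 1.
* Zero-variance regression target → explicit error (R² undefined).
* Perfect predictions → RMSE 0, RPD reported as +inf (flagged), never a
  division error.
* RFE CV-RMSE ties → smaller subset; SVR grid ties → smaller C, then
  larger ε; Boruta features undecided at the iteration cap → Tentative.
* The R² printed form with ŷ−ȳ in the numerator (which would not equal
  1 at perfect prediction) is treated as a typographical slip; the
  residual form is implemented.

## Known limitations

* The ELM is fitted per image; flight-level or stage-level calibration
  (the field-practice alternative) is not implemented.
* GLCM maps support the 3×3 window only in the vectorized path; larger
  windows would need the naive path.
* Boruta Z-scores use impurity importances; permutation importance is
  noted as an alternative but not implemented.
* The SVR grid is fixed rather than adaptive; no uncertainty intervals
  on the metrics.
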