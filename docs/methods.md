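# Methods

## Scientific setting

Mid-infrared attenuated-total-reflection (ATR-FTIR) spectra of blood plasma
summarize the sample's global biochemistry: the fingerprint region
(1800–900 cm⁻¹) is dominated by the protein amide I/II bands with
contributions from lipid esters, phosphates and carbohydrates; the high
region (3050–2800 cm⁻¹) by CH₂/CH₃ stretching of lipid acyl chains. In
multiple sclerosis, demyelination and blood–brain-barrier leakage are
expected to shift the plasma lipid/protein balance: ester C=O (~1740 cm⁻¹),
olefinic =C–H (~3013 cm⁻¹) and CH bands up, amide I (~1650 cm⁻¹) down. The
package asks whether those shifts are detectable by supervised classification
of preprocessed spectra and whether the discriminating wavenumbers coincide
with those bands.

## Preprocessing model

Stages run in a fixed order: replicate averaging (compare subjects, not
spectra) → region cut (closed interval; the default grid spacing 900/620
cm⁻¹ makes the fingerprint cut exactly 621 variables, the high cut ~173) →
rubber-band baseline → second derivative (optional) → vector normalization.

- **Rubber-band baseline.** The baseline is the lower convex hull of the
  (ν, A) point set, computed by Andrew's monotone chain and evaluated by
  linear interpolation between hull vertices. The corrected spectrum is ≥ 0
  up to float round-off and exactly 0 at hull contacts; the operation is
  idempotent. Tests verify the production hull against an O(n²)
  gift-wrapping construction.
- **Savitzky–Golay second derivative.** 13-point window, polynomial order 2
  (for a symmetric window the second-derivative coefficients of orders 2 and
  3 coincide, so this matches the common convention when only the point
  count is specified). `scipy.signal.savgol_filter` with `mode="interp"`
  supplies the edge handling: the outermost (window−1)/2 points evaluate the
  edge-fitted polynomial, keeping output length equal to input length.
  Coefficients are scaled by the grid spacing, so the derivative is in
  absorbance/(cm⁻¹)² and polynomial-exactness is grid-independent.
- **Order of operations.** Baseline correction precedes the derivative on
  both tracks (the derivative largely cancels smooth baselines, so applying
  both is harmless); vector normalization is always last. Classifiers
  consume per-subject derivatives; class-mean ± SD spectra are for display.

Band ratios are computed on baseline-corrected, vector-normalized
*absorbance* spectra; since all three ratios are quotients of intensities or
areas of the same spectrum, they are invariant to the normalization. Amide
integration windows default to 1700–1600 (amide I) and 1600–1500 cm⁻¹
(amide II), bracketing the 1650/1547 peaks; both are configurable as no
standard bounds exist. Peak intensities are window maxima (half-width
default 5 cm⁻¹, ties toward the lower wavenumber); 1739/1740 name the same
ester band.

## Synthetic cohort generator

The generator states the emulated world; its defaults are not free knobs.
Cohort: 40 HC + 45 MS subjects, 5 replicates each, grid 900–4000 cm⁻¹ at
900/620 cm⁻¹ spacing. MS subjects carry EDSS scores uniform within the mild
(0.5–3.0, 32 subjects) or moderate/severe (3.5–7.0, 13) band, and onset
times drawn from the study's coarse duration histogram with the ≤10 y : >10 y
split fixed at 27 : 18; both stay missing for controls.

Each spectrum is `gain · (Σ Gaussian bands + baseline) + noise`:

- 19 Gaussian bands at literature-assigned plasma wavenumbers (amide I
  dominant at 0.5 absorbance units; FWHM 15–50 cm⁻¹). Gaussians are used
  because they have a closed-form area for oracle tests; the analysis never
  assumes a line shape.
- Per-subject band amplitudes are lognormal with unit median and CV 0.10
  (positivity, median-preserving), shared across a subject's replicates.
- Disease effects are per-band multiplicative factors on MS amplitudes.
  Defaults (moderate): 1740 ×1.15, 3016 ×1.12, 2927 ×1.10, 1453 ×1.08,
  1650 ×0.95 — directions from the emulated study, magnitudes chosen here
  since none are published on a common scale. With these defaults the
  models reach AUC ≈ 0.6–0.9, i.e. a detectable but imperfect signal,
  matching the qualitative difficulty of the real problem.
- Baseline: per-subject random cubic polynomial scaled by 0.01 absorbance;
  replicate gain lognormal with CV 0.05; additive white noise SD 0.002
  (SNR ~250 at the amide I peak, typical of averaged liquid-cell spectra).

What the generator does **not** emulate: ATR penetration-depth dispersion,
Mie/resonant scattering, water-vapour lines, session drift, non-Gaussian
band shapes, and correlated biochemical covariation between bands. A green
parameter-recovery test therefore establishes that the pipeline recovers
planted multiplicative band effects under realistic noise — not that the
real biological effect is of any particular size.

## Classification and validation

- **PCA-LDA.** Full-SVD PCA on the training fold; the smallest PC count
  whose cumulative explained variance exceeds 0.95 (24/8 PCs are typical for
  fingerprint/high-region training sets of this size); two-class LDA on the
  scores with empirical priors. The pooled within-class covariance gets a
  ridge of 1e-8·trace/dim (absolute floor 1e-8 when the scatter is exactly
  zero) because PC scores can be near-collinear inside folds.
- **PLS-DA.** PLS1 (`sklearn` NIPALS, `scale=False`) on a {0,1} response
  with mean-centering only — spectra are already vector-normalized, so unit
  variance scaling is not applied. The continuous predicted response is the
  ROC score; class by threshold 0.5.
- **Random forest.** Own bagging over `sklearn` CART trees (Gini, grown to
  purity, `m_try` candidate features per split) with bootstrap indices drawn
  in the package so each tree's out-of-bag subjects are recorded — required
  for OOB accuracy and permutation importance. Score = fraction of trees
  voting MS. 500 trees by default; the `m_try` grid contains √p plus the
  region-typical larger value (35 or 165) so the tuning path can reach both.
- **Protocol.** Stratified subject-level 75/25 split (test size = round(n/4)
  per class: 11 MS + 10 HC at default sizes); 10×-repeated stratified
  5-fold CV on the training subjects; tuning by mean CV accuracy with ties
  broken toward the simpler value; refit on the full training set; single
  test-set evaluation. Stratification is used throughout because the classes
  are small and the reference tooling in this field stratifies by default.
  All data-driven steps (centering, PCA, deflation, trees) are re-estimated
  inside every fold; a subject-id audit test asserts no train/test overlap.
- **Permutation test.** Labels permuted at subject level; the full protocol
  re-run per permutation; p = (1 + #{perm ≥ observed})/(n_perm + 1), never
  zero. The orchestration layer offers a "fixed" mode that re-runs the
  protocol at the observed tuning value instead of re-tuning the grid, for
  use when the compute budget cannot absorb n_perm × grid × CV model fits
  (the forest especially); the library default is the full re-tune.
- **Smoothed ROC.** Binormal fit after a rank-based normal transform of the
  pooled scores; AUC = Φ(Δμ/√(σ₀²+σ₁²)). Zero within-class score variance
  falls back to the empirical curve with a flag.
- **Importance.** PLS: Σ_h |b_jh|·SSY_h / Σ_h SSY_h with b_jh the
  per-component coefficient contribution and SSY_h the response sum of
  squares explained by component h. RF: per-tree OOB accuracy before minus
  after permuting one predictor, averaged over trees and divided by its
  standard error (sd/√n_trees); variables a tree never splits on contribute
  exactly zero. ROC filter (PCA-LDA surrogate): per-variable Mann–Whitney
  AUC folded to max(AUC, 1−AUC) so ranking is direction-agnostic. Raw RF
  values may be negative; plotting clips at zero but the stored profile is
  raw.
- **Subgroups.** Test-set sensitivity is recomputed within EDSS (≤3 vs >3)
  and onset (≤10 y vs >10 y) MS subgroups; specificity comes from the one
  HC test set and is constant across rows by construction. (Published
  subgroup tables that vary specificity across rows imply re-partitioned
  test sets; this package keeps the single-split definition and documents
  the difference.)

## Numerical conventions and edge cases

- Grid stored ascending; files in descending instrument order parse to the
  same object. Grid uniformity enforced at 1e-6 relative tolerance (guards
  trapezoidal integration); region bounds applied with 1e-9 relative slack
  so accumulated float grids cut reproducibly.
- CSV dialect: comma, "." decimal, UTF-8, mandatory header; reserved
  metadata columns `subject_id, replicate, class_label, edss, onset_years`;
  missing numeric metadata as empty fields. Round-trips are exact on
  metadata and ≤1e-12 on intensities (shortest-repr float formatting).
- Degenerate statistics: zero pooled variance with equal means → p = 1;
  with unequal means → p = 0, flagged degenerate. Star coding uses strict
  thresholds (p = 0.05 codes "ns") while the significance decision rule is
  "0.05 or less"; the two conventions are kept as distinct contracts.
- Empty subgroups report NaN instead of raising; an all-zero spectrum
  cannot be vector-normalized and raises; a non-positive ratio denominator
  raises naming the subject.
- Master seed → stage seeds via SHA-256 of `"{seed}:{stage}"` (mod 2³¹−1),
  so stages are independent and the whole run is reproducible bit-for-bit.

## Known limitations

- The generator's independence of band amplitudes across subjects is
  optimistic; real plasma components covary, which typically *helps*
  multivariate models, so synthetic accuracies are conservative in that one
  respect while ignoring instrument artifacts that would hurt.
- The binormal ROC smoother assumes unimodal score distributions; forest
  vote fractions with few trees are coarse and can make the smoothed AUC
  deviate from the empirical one.
- The OOB permutation importance is computed per fitted forest; it is not
  re-estimated across CV repeats, so its sampling variability is not
  reported.
- Only two-class problems are supported; no probability calibration, no
  vendor binary formats (OPUS/JCAMP-DX), no EMSC or atmospheric correction.
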