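# Methods

This note records the models, conventions and design decisions behind
`leafspec`, in the spirit of a model-documentation page: what each stage
assumes, which knobs matter, and what the synthetic data does and does not
establish.

## Acquisition model and calibration

A hyperspectral line-scan camera produces a cube of raw counts
`I[row, col, band]`. Counts mix the scene's reflectance with the lamp
spectrum, optics and dark current, so reflectance is recovered against a
~99 %-reflectance white board `W` and a closed-shutter dark frame `D`:

    R = (I − D) / (W − D)

Pixels with reference contrast `W − D ≤ 1e−6` (counts scale) are set to NaN
rather than divided: a silent division there produces unbounded artifacts
that would otherwise leak into masks and means. Calibrated values are *not*
clipped to [0, 1] — specular highlights legitimately exceed 1, and clipping
would bias the SNV/MSC statistics computed later. Cubes are always
rows × cols × bands in memory regardless of on-disk interleave; the ENVI
dialect (ASCII header + little-endian binary, bil/bip/bsq) and an HDF5
container (`/data`, `/wavelengths` + attributes) are both supported, the
latter bit-exact under round trip.

Spectral ranges follow the trimmed camera spans: Range I 423–975 nm
(Vis-NIR), Range II 970–1684 nm (SWIR), Range III both cameras combined.
Band intervals are closed — the named endpoints are included band positions.
When the two cameras are concatenated for Range III, SWIR bands below
975 nm duplicate the top of the Vis-NIR axis and are dropped; on the default
204-band uniform grids this removes 2 bands, leaving 406. Nearest-band
lookup breaks ties toward the lower index.

## Segmentation

The leaf is segmented on a single gray band — 800 nm (Vis-NIR) or 1000 nm
(SWIR) — where plant tissue sits on its NIR high-reflectance plateau and is
far brighter than the platform. Otsu's criterion (256-bin histogram,
threshold at the bin edge maximizing between-class variance, ties to the
lowest edge) splits the histogram; the class with the larger mean gray value
is declared foreground. That rule, rather than "values above threshold",
makes the segmentation explicit about *why* the leaf is foreground and
behaves predictably if contrast inverts. The largest 4-connected component
is retained and holes filled, so stray bright pixels cannot contaminate the
mean spectrum. Invalid (NaN-calibrated) pixels count as background.

The whole leaf is the region of interest, vein included. The reference
assay grinds the leaf *without* the main vein, so the spectral ROI and the
assayed material differ slightly; this mismatch is inherent to the protocol
being modelled and is left as-is.

## Pretreatment

All pretreatments act row-wise on a samples × bands matrix and are applied
to the *full trimmed range before* any wavelength subsetting — SNV and MSC
statistics are whole-spectrum quantities, so selected-band indices always
refer to preprocessed full-range columns.

* **SNV**: `x → (x − mean(x)) / sd(x)` with the n−1 sample standard
  deviation. Exactly removes per-spectrum affine scatter.
* **MSC**: per-row least squares `x ≈ a + b·ref`, corrected row
  `(x − a)/b`; `ref` is the training-set column mean and is frozen into the
  preprocessing state. Re-estimating it on test or pixel spectra would leak
  information and make pixel maps depend on the scene; the frozen reference
  makes the transform a fixed function.
* **SG first derivative**: Savitzky–Golay local polynomial fit, default
  window 7 / order 2 (a common chemometrics choice at ~3.5 nm band spacing;
  both exposed). The derivative is taken with respect to band index — on the
  uniform synthetic grids this is proportional to d/dnm — and edges come
  from one-sided polynomial fits on the first/last windows.

A noteworthy interaction, visible in the tests: because a spectrum's
standard deviation depends on protein through the absorption wells, SNV can
*relocate* predictive information — after SNV, bands on the flank of the
1450 nm water feature become near-perfect protein proxies even though
protein never absorbs there. Wavelength-recovery claims are therefore
evaluated on untransformed spectra, and selector output on transformed
spectra should be interpreted as "informative for the model", not
"chemically absorbing".

## RMSECV and the selectors

All selectors score candidate band subsets by RMSECV: k-fold (default 10)
cross-validated RMSE of a mean-centred univariate PLS with 1..max_pcs
components, minimized over the component count. One fold partition is drawn
per selector call and reused for every candidate so scores are comparable.
NIPALS components are nested, so a single fit per fold yields the
coefficient path for every component count — a k-fold scan costs k fits.
The inner-model cap defaults to 10 latent components for selectors (kept
deliberately below the final-model cap of 30; selector scoring needs
ranking fidelity, not a fully tuned model).

* **SPA** grows, from every candidate start column, a chain of mutually
  near-orthogonal columns (each step appends the column with maximal
  residual norm against the span of the chain); every prefix of length
  k_min..k_max (defaults 2..25) is scored and the global minimizer wins.
  Ties prefer fewer variables, then the lower start index. Chains stop
  early on rank collapse (all residual norms ≤ 1e−12).
* **CARS** runs N Monte Carlo rounds (default 1000). Each round fits PLS on
  a random 80 % subsample (without replacement) restricted to the live set,
  weights variables by normalized |coefficient|, and applies the enforced
  exponentially decaying retention count `ceil(r_i·p)` with
  `r_i = a·e^{−k·i}`, `a = (p/2)^{1/(N−1)}`, `k = ln(p/2)/(N−1)` — all p
  variables at round 1, exactly 2 at round N. The adaptive reweighted
  sampling step draws that many *distinct* variables with probability
  proportional to weight (weighted sampling without replacement), so the
  live-set size tracks the schedule exactly while low-weight bands can
  still survive by luck. A literal draw-with-replacement-then-deduplicate
  step was considered and rejected: deduplication shrinks the set ~0.63×
  per round on top of the schedule and collapses any run within ~20 rounds,
  making long runs meaningless. Each round's live set is scored by RMSECV
  and the best recorded set is returned (ties: smaller set, then
  lexicographic).
* **Random frog** walks subset space: a candidate subset of normally
  perturbed size (sd = θ·current, θ = 0.3) is proposed by weight-guided
  growth (fit PLS on the union with a random candidate pool three times the
  deficit, keep the top-|coefficient| bands) or shrinkage (drop the
  lowest-weight members), accepted if RMSECV improves, and otherwise with
  probability η·(current/candidate), η = 0.1. Initial size is max(2, p/10).
  Each band's visit frequency over n_iter iterations (default 1000) is its
  selection probability; the top-k (default 10) most probable bands are
  returned, ties to the lower index. The growth move is the main point of
  freedom in this family of algorithms; the weight-guided union variant was
  chosen because per-candidate RMSECV evaluation costs an extra factor of p
  per iteration for no observed gain in recovery.

All three selectors are deterministic given their seed.

## Regression

**PLS** is univariate NIPALS on mean-centred data, no autoscaling (scaling
is the pretreatment's job). Predictions through the latent path and through
the collapsed coefficient vector agree to 1e−10; a deflation step with zero
weight norm truncates the model and flags it. The latent-component count is
chosen by 10-fold CV RMSE (ties → fewer), capped at
min(n_fold_train − 1, p) and by default at 30.

**LS-SVM** uses the RBF kernel `K(x,z) = exp(−‖x−z‖²/σ²)` — the σ²
denominator convention is chosen so the tuned parameter is directly the σ²
reported in chemometrics tables — and solves the (n+1)×(n+1) saddle-point
system `[[0, 1ᵀ],[1, K + I/γ]]·[b; α] = [0; y]`. Hyperparameters come from
exhaustive CV over γ, σ² ∈ {2⁻⁵, 2⁻³, …, 2¹⁵} (ties: smaller γ, then larger
σ² — the less-overfitting, smoother corner). Pairwise distances are computed
once per grid search.

## Evaluation

The train/test split permutes indices from a seed and takes
round-half-up(0.7·n) training samples — 135/58 at n = 193. R² is the
coefficient of determination 1 − SS_res/SS_tot on the test set (not a
squared correlation), RMSE is in g/100 g, and RPD = sd(y; n−1)/RMSE with
classes fail (<1.4), average ([1.4, 2)), excellent (≥2).

The Kjeldahl formula is implemented as
`X = (V1−V2)·C·0.0140·F·100 / (m·(V3/100))` with defaults C = 0.05 mol/L,
m = 0.3 g, V3 = 50 mL, F = 6.25. The denominator grouping reads V3/100 as
the assayed aliquot fraction, which makes the output dimensionally g/100 g;
the typeset source formula is ambiguous about this grouping, so the chosen
reading is documented here and pinned by a unit test
((5.0−0.2, 0.05, 0.3, 50) → 14.0).

## The comparison grid

`run_grid` evaluates ranges × pretreatments × selectors × models (default
3×3×4×2 = 72 rows) on *one* shared split and one shared CV fold plan. For
each combination: trim range → fit pretreatment on training rows → select
wavelengths on training rows → tune (PCs or γ, σ²) by CV on training rows →
refit on all training rows → evaluate on test rows. Selection is computed
once per (range, pretreatment, selector) and shared by the PLS and LS-SVM
rows. A failing combination becomes a `status="failed"` row rather than
aborting the run; outputs carry no timestamps so reruns are byte-identical.
Test rows are touched only by the frozen transform and the final model — a
test perturbs them and asserts selection and hyperparameters are unchanged.

## Pixel maps

Each foreground pixel's full-range spectrum goes through the *training*
pretreatment state, is subset to the selected bands, and is predicted by the
trained model — the exact order used in training. Pixels whose pretreatment
is undefined (e.g. a constant spectrum under SNV) become no-data and are
counted. Rendering uses a sequential colormap; passing the training-set
protein range as color limits keeps shading comparable across leaves. For
a linear chain (no pretreatment + PLS) the map mean equals the prediction
of the mask-mean spectrum exactly; with SNV or a kernel model this holds
only approximately, which is why the exact identity is asserted only for
the linear configuration.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:

* **Grids**: 204 uniformly spaced bands per camera over 423–975 and
  970–1684 nm. Real instruments have non-uniform physical band centres;
  none are published for this problem, so uniform spacing is a stand-in and
  is flagged as such.
* **Baseline**: a smooth green-vegetation curve — logistic red edge onto the
  NIR plateau, Gaussian green peak (555 nm), shallow red dip (660 nm),
  water dip (1450 nm) — bounded in (0, 1) over the full span.
* **Protein signal**: reflectance is depressed at Gaussian absorption
  centres (defaults: 560/660 nm Vis-NIR; 1180/1510 nm SWIR, widths 30 nm)
  by the factor `1 − β·p·A(λ)` with β = 0.012 per (g/100 g), so reflectance
  decreases monotonically in protein at the centres. The SWIR centres sit
  in the 1170–1350 nm region and the N–H overtone region near 1510 nm where
  protein features concentrate; configurations implying negative
  reflectance are rejected.
* **Protein distribution**: uniform over 10–46 g/100 g (spanning reported
  leaf values), 193 samples.
* **Scatter/noise**: per-spectrum gain ~ N(1, 0.05), offset ~ N(0, 0.01),
  band noise ~ N(0, 0.003) — the distortions SNV/MSC are designed to
  remove; the suite verifies ≥90 % of the gain/offset-attributable
  replicate variance disappears under either correction.
* **Leaf scenes**: an elliptical blade with a midrib and six branching
  veins; vein pixels carry 0.35× the blade protein, plus a smooth
  low-amplitude spatial field (sd 0.8 g/100 g). White cubes have a smooth
  illumination profile, dark cubes a low pedestal, and the raw cube is
  assembled exactly as `D + R·(W−D)`, so calibration inverts the
  construction to machine precision.
* **References**: true protein + N(0, 0.3 g/100 g) assay noise is converted
  to a titration volume by inverting the Kjeldahl formula and re-reported
  through the forward formula, so reference tables are internally
  consistent.

What the synthetic data does *not* model: radiative-transfer leaf optics,
camera point-spread/smile, non-uniform band centres, shadows, touching
leaves, and covarying constituents (water, cellulose) that make real
spectra far more collinear with protein. Passing tests therefore establish
the correctness and discipline of the pipeline — not field-level accuracy;
the near-perfect R² on synthetic data reflects the generator's single
dominant signal, and real-leaf performance will be lower.

## Problem sizes used in tests and the acceptance script

The study-scale checks (selector recovery, headline SNV+SPA+LS-SVM chain,
pixel map) run at the full default conditions: 193 samples, 204 SWIR bands,
80×100-pixel scenes, frog at 1000 iterations, CARS at 200 Monte Carlo runs
(the recorded-best-subset result is stable well before the 1000-run
default). Grid-integrity checks (72-row cardinality, leakage, byte-identical
reruns) are scale-free properties and run at 72 samples × 60 bands with
CARS/frog at 40 iterations so the whole suite stays fast; the structure and
code path are identical to a full-size run.

## Known limitations

* SPA evaluates every start column; on very wide matrices (Range III) this
  is the slowest stage. Restrict `starts` or lower `k_max` for quick scans.
* The LS-SVM is dense — all training samples are support vectors — so
  pixel-map prediction scales with n_train × n_pixels kernel evaluations.
* Random frog's proposal family is one of several in the literature; its
  selection probabilities are comparable within a run, not across variants.
* The 7:3 split is a single random split, as in the emulated protocol;
  repeated splits would be needed to attach uncertainty to R²/RPD.
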