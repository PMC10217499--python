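# Methods

This note documents the statistical model, the synthetic data generator,
every numerical choice with a default, and the package's known limitations.
All defaults below are the frozen package defaults; they are also what the
test suite and `scripts/acceptance.py` exercise.

## 1. Data model

A `Spectrum` is a pair (wavenumber grid, absorbance vector) plus metadata.
The grid must be strictly increasing and uniform; uniformity is checked
with a tolerance of 1e-9 **relative to the step**, so instrument-style
grids that are uniform up to float rounding pass and genuinely irregular
grids fail. Descending input (common in FTIR exports) is auto-resorted.
Intensities must be finite.

A `SpectraSet` is a shared grid, an (n, p) intensity matrix and a metadata
frame with columns `spectrum_id` (unique), `fish_id`, `day` (int) and
`fibre_id`. CSV I/O supports a long format (one row per point) and a wide
format (one row per spectrum). Floats are written with `%.17g` and read
with round-trip float parsing, so `read(write(S)) == S` exactly.

The default measurement grid is 600–2500 cm⁻¹ at 2 cm⁻¹ (951 points);
analysis happens on the fingerprint crop 900–1780 cm⁻¹ (441 points).

## 2. Synthetic generator

Each simulated spectrum is

```
y(w) = scale · [ P(w) + Σ_b  F_fish · G_fibre · a_b · e_b(day) · g_b(w) ] + ε(w)
```

* `g_b(w)` — Gaussian band of unit peak height, parameterised by center and
  FWHM. The inventory holds 17 bands: protein amide I/II/III components,
  nucleic-acid ribose/phosphate bands, lipid ester and acyl bands, and
  neutral background bands. Band roles are `fresh` (amplitude decreases
  with storage), `aging` (increases) or `neutral` (flat).
* `a_b` — base amplitude. The dominant amide I component (1650 cm⁻¹) has
  amplitude 1.0; others are scaled relative to it. The 1176 cm⁻¹
  nucleic-acid band uses amplitude 0.25 with FWHM 8 so that it remains
  robustly quantifiable after baseline correction (see §3 on the
  undershoot artifact).
* `e_b(day)` — day-effect factor, piecewise-linear through anchors.
  Fresh bands: 1.0 at day 0 → 0.5 at day 7 → 0.35 at day 15, with the
  intermediate days 3 and 5 at 0.74 and 0.70. Aging bands: 1.0 → 1.6 →
  1.9, with days 3 and 5 at 1.30 and 1.38. Days 3 and 5 are deliberately
  compressed toward each other — degradation chemistry plateaus
  mid-storage — making those the hardest classes to separate, while still
  keeping every class learnable. These factors (and the band-amplitude
  choices above) were calibrated once by simulation and then frozen.
* `F_fish`, `G_fibre` — lognormal heterogeneity factors, σ = 0.10 per fish
  and σ = 0.15 per fibre, shared across all bands of a spectrum so that
  biological variability is correlated across the spectrum rather than
  i.i.d. per band.
* `P(w)` — smooth random baseline: an order-3 polynomial in the scaled
  wavenumber with coefficient scale 0.05.
* `scale` — uniform(0.8, 1.2) optical-thickness factor.
* `ε(w)` — i.i.d. Gaussian noise, σ = 0.005 absorbance units.

Two neutral broad bands at 650 cm⁻¹ and 2120 cm⁻¹ (water-association
region) give the region outside the fingerprint window genuine structure;
without them the 1800–2500 cm⁻¹ stretch is dead flat and the polynomial
baseline fit oscillates through the fingerprint region, biasing small
bands (§3).

The default campaign (`default_scenario("paper_effects")`) is 3 fish × 39
fibres × 7 storage days (0, 1, 3, 5, 7, 9, 15) = 819 spectra, seed 42.
A `null_effects` scenario sets every day-effect to 1.0 and is used for
negative controls. `generate_physchem` produces per-(fish, day, replicate)
physicochemical values — pH, protein solubility, proteolysis, L\*a\*b\*
colour — where solubility is coupled to the same fresh-band day factor the
spectra use (75 − 30·factor + noise), so spectra–chemistry correlations
are real, not coincidental.

All randomness flows through one `numpy.random.default_rng(seed)`;
identical seeds give bit-identical campaigns.

**What the generator emulates:** band-level biochemistry of storage,
fish/fibre heterogeneity, thickness scaling, baseline drift, detector
noise, a physicochemical panel coupled to the spectra.

**What it does not emulate:** Mie/resonant-Mie scattering distortions,
water-vapour and CO₂ rotational lines, detector nonlinearity and fringing,
spatial fibre maps or within-fibre gradients, day-to-day instrument drift,
and non-Gaussian band shapes (Lorentzian/Voigt wings).

## 3. Preprocessing

`preprocess` applies, in order: optional reference-spectrum subtraction →
baseline correction on the **full** grid → crop to 900–1780 cm⁻¹ →
vector normalisation.

* **Baseline** — iterative modified-polynomial ("ModPoly") fitting: fit an
  order-5 polynomial, replace the working vector by the elementwise
  minimum of data and fit, repeat until the fitted curve changes by less
  than tol = 1e-6 (relative) or 200 iterations. The implementation builds
  the hat matrix once via QR (fit = QQᵀy) and iterates all spectra as a
  matrix with per-row convergence tracking, which makes an 819-spectrum
  campaign take seconds. Known artifact: over regions with little
  structure the converged baseline can undershoot slightly (order 1–2% of
  the amide I height), which is why small analytical bands should not sit
  next to long empty stretches (cf. the background bands in §2).
* **Crop** — inclusive window; cropping to an empty window raises.
* **Normalisation** — unit Euclidean norm, applied **after** cropping so
  that out-of-window intensity cannot influence in-window scale
  (`normalise_before_crop=True` is available for comparison). Zero-norm
  spectra raise a `NormalisationError` naming the offending
  `spectrum_id`.

Baseline correction runs before cropping on purpose: the polynomial needs
the full recorded range to be well-conditioned.

## 4. PC-DA

* **PCA** — `sklearn` full-SVD PCA; loading signs are fixed so the
  largest-magnitude element of each loading is positive, making results
  reproducible across library versions.
* **k selection** — if `k` is not given: the smallest k whose cumulative
  share of a 30-component probe decomposition reaches 95%, capped at 15.
  The probe normalisation is a deliberate shortcut (the trailing
  noise-floor components never matter for discrimination).
* **Discriminant** — with PC-score group means and pooled within-group
  covariance W: two groups use w = W⁻¹(m₁ − m₂) directly; more groups
  solve the generalised symmetric eigenproblem B v = λ W v
  (`scipy.linalg.eigh`). W is regularised as W + ridge·trace(W)/k·I with
  ridge = 1e-6 by default (scale-free; 0 allowed for well-conditioned
  problems, singular W then raises `SingularCovarianceError`).
* **Sign convention** — the first group's mean canonical score is made
  positive, so positive F1 peaks always mark bands elevated in the first
  listed group.
* **Membership** — softmax over −½·Mahalanobis² to each group mean in PC
  space (equal priors); argmax gives the `predicted` column.
* **F1 vector** — F1 = wᵀL (loadings L). Because PCA scores are centred,
  score(x) = F1·(x − mean_spectrum) holds to machine precision; the test
  suite asserts it at 1e-8.
* **Biomarker extraction** — `scipy.signal.find_peaks` on |F1| (with
  endpoint handling), ranked by |score|, keeping the top fraction
  (default 25%); the sign of F1 at the peak assigns the band to a group.
* **Persistence** — JSON round-trip of all fitted arrays; a reloaded
  model scores new spectra identically (asserted at 1e-10).

## 5. Classification and embedding

* **SVM** — `StandardScaler` + `SVC(kernel="rbf", C=1, gamma="scale")` in
  a single pipeline, evaluated with `StratifiedKFold(shuffle=True,
  random_state=seed)` and `cross_val_predict`; the confusion matrix pools
  all folds. The scaler is not cosmetic: vector-normalised spectra have
  tiny pairwise distances, `gamma="scale"` then drives the RBF kernel
  toward an all-ones matrix and accuracy collapses to near-chance.
  Per-feature standardisation restores contrast. Classes with fewer
  members than folds raise an error naming the class.
* **t-SNE** — run on the first 5 PC scores (not raw spectra), perplexity
  50, `init="pca"`, fixed seed. Perplexity ≥ n raises; perplexity above
  n/3 warns.

## 6. Marker statistics

* **Peak intensity** — maximum within ±5 cm⁻¹ of the target (mode
  `"max"`, default) or linear interpolation at the exact wavenumber
  (mode `"interp"`). Windows outside the grid raise.
* **Band ratios** — each marker band divided by the amide III reference
  at 1186 cm⁻¹; a non-positive denominator sets `denominator_ok=False`
  and NaN ratios for that spectrum instead of failing the whole set.
  Ratio checks against raw band structure are best done on
  baseline-corrected but **un-normalised** spectra (`normalise=False`),
  since unit-norm scaling mixes all bands into the denominator.
* **Group comparison** — one-way ANOVA (`scipy.stats.f_oneway`) with
  Tukey HSD post-hoc (`statsmodels`) summarised as compact letter
  display; groups sharing a letter are statistically indistinguishable at
  α = 0.05. A degenerate all-equal input returns F = 0, p = 1. Groups
  with fewer than 2 observations raise.
* **Physicochemical correlation** — fibres are tri-partitioned within
  each (fish, day) cell by a seeded permutation into three pseudo-
  replicates; block-mean band intensities are paired with the replicate
  physicochemical values by (fish, day, replicate) key and correlated
  with Pearson r (two-sided p). Key mismatches raise rather than silently
  inner-joining.

## 7. Problem sizes and runtime

The default campaign (819 × 951) preprocesses in ~2 s and completes a
10-fold SVM CV in ~30 s. The full test suite (unit + property +
acceptance, including a 1000-replicate ANOVA calibration check) runs in
~3–4 minutes.

## 8. Limitations

* The generator is band-additive with Gaussian shapes; it cannot produce
  the scattering and saturation pathologies real micro-spectroscopy shows,
  so preprocessing robustness claims extend only to baseline/scale/noise
  distortions of the modelled kind.
* PC-DA assumes shared within-group covariance and works in a truncated
  PC space; with very small groups or k close to group size the pooled
  covariance estimate is unstable (the ridge mitigates but does not cure
  this).
* Day-effect factors are deterministic per day — there is no per-fish
  storage-rate variation, so between-fish variance is likely optimistic
  relative to real campaigns.
* Resubstitution accuracy is reported for diagnostics only; all
  generalisation claims use cross-validation.
* The compact letter display uses a standard insertion–absorption
  heuristic; for many groups it is not guaranteed to be the minimal
  letter assignment.
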