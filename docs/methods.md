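# Methods

This note documents the models and procedures implemented in `paddywave`,
the parameter choices that matter, what the synthetic trial generator does
and does not emulate, and the numerical conventions that pin down every
result bit-for-bit.

## The estimation problem

A plot's grain yield (g·m⁻², from a 1 m² harvest quadrat) is regressed on
features of its canopy reflectance spectrum R(λ), λ ∈ [350, 2500] nm,
measured at four phenological stages: elongation, heading, flowering, milky.
Yield integrates the whole season, so features from several stages are fused
(column-wise concatenation of stage-tagged features) and all 15 non-empty
stage subsets are compared. Two feature families are compared — derivative
bands + vegetation indices (FD-VI) and the same plus wavelet cells
(CWT-FD-VI) — under two regressors (stepwise linear, random forest),
giving a 15 × 2 × 2 model grid.

## Spectral representations

All spectra live on the canonical 1 nm grid 350…2500 nm (2151 bands).
Instrument grids (1.3 nm below 1000 nm, 2 nm above, for a typical full-range
field spectroradiometer) are unified by linear interpolation; extrapolation
is refused, because edge features (the tri-edge windows, the SWIR water
wells) are exactly where silent extrapolation does damage.

* **OR** — Savitzky–Golay smoothing, window 11, polynomial order 3. The
  window/order pair is a common spectroscopy default; both are exposed in
  the config and pinned by tests (an 11-point cubic filter reproduces cubic
  polynomials to 1e-10 and roughly halves white noise at these settings).
* **FD** — first derivative of OR by central differences (one-sided at the
  grid ends), divided by Δλ, so units are reflectance·nm⁻¹. The pipeline
  always smooths before differentiating.
* **CR** — continuum removal S_cr = R/R_C0, where R_C0 is the piecewise-
  linear upper convex hull of (λ, R) (Andrew monotone chain). S_cr is exactly
  1 at hull vertices (grid endpoints included), lies in (0, 1], and the
  transform is idempotent. Requires R > 0.
* **CWT** — W_f(a,b) = Σ_λ f(λ)·a^{-1/2}·ψ((λ−b)/a)·Δλ, the direct
  discretization of the defining integral, at dyadic scales 2¹…2¹⁰.

### CWT numerical conventions

The mother wavelet is the L2-normalised Mexican hat
ψ(x) = (2/(√3·π^{1/4}))(1−x²)e^{−x²/2}. The analysis that this package
follows does not name its wavelet; the Mexican hat is the de-facto standard
for vegetation-spectra CWT (smooth, symmetric, one oscillation — matches
absorption-well geometry) and is the configurable default here.

Boundaries use half-sample symmetric (mirror) extension. This matters: at
scale 2¹⁰ the kernel support (±8a, where ψ < 1e-12) spans ±8192 nm, far
beyond the 2151-band grid. The kernel is truncated at |x| = 8, so the
discrete sum equals the untruncated one to ~1e-12. Tests verify the
transform against (a) a brute-force mirror-extended sum on small grids
(≤1e-8) and (b) adaptive quadrature of the defining integral of an analytic
Gaussian, extended with the same mirror rule (≤1e-6 relative at all ten
scales). For scales up to 2⁸ the coefficient of a centered Gaussian bump is
maximised exactly at the bump center; at 2⁹–2¹⁰ the extension, not the bump,
dominates the plane's shape, which is why screening results at those scales
should be read with care.

## Features

* **Vegetation indices** from single-band reflectances R = OR(670),
  NIR = OR(800): NDVI = (NIR−R)/(NIR+R), DVI = NIR−R, RVI = R/NIR,
  EVI = 2.5(NIR−R)/(1+NIR+2.4R). Band positions are configurable; no band
  averaging. RVI is implemented as R/NIR — the form used by the analysis
  this package reproduces — although most of the literature uses NIR/R; a
  `rvi_inverted` switch selects the conventional form. Only NDVI's yield-
  correlation sign is asserted in tests, since the two RVI conventions flip
  sign.
* **Tri-edge parameters** of the FD spectrum over red 680–760, blue 490–530,
  yellow 560–640 nm windows (window bounds follow the usual red/blue/yellow
  edge convention and are configurable): D = max FD in the window (even
  where FD is negative throughout, as on blue/yellow edges), λ = wavelength
  of that maximum (smallest on ties), SD = trapezoidal integral of FD over
  the window. SD_r telescopes to R(760)−R(680) up to a boundary term
  h²(R″(760)−R″(680))/4 — the tests exploit this identity.
* **Edge combinations**: the eight difference/ratio/normalized-difference
  combinations of SD_r, SD_b, SD_y. Zero denominators propagate as missing
  values, never exceptions.
* **Screened bands/cells**: per stage, Pearson r of every FD band (and every
  CWT cell) with training-trial yield; predictors with |r| above the
  two-tailed significance bound r* = t*/√(t*²+n−2) at α = 0.05 are picked
  greedily in decreasing |r|, suppressing neighbours within 10 nm at the
  same scale, at most 5 per stage and transform. The selection rule
  (top-5, 10 nm separation) is this package's reproducibility choice — the
  emulated analysis does not state one — and is config-overridable.

## Models and evaluation

**Stepwise regression (MSR).** Forward entry / backward removal on
partial-F p-values (for a single variable the partial F equals the squared
coefficient t, which is what is computed): at each pass the candidate with
the smallest entry p < 0.05 enters, then retained variables with p > 0.10
are removed worst-first, until a fixed point. The 0.05/0.10 pair is the
common default; both are configurable. Candidates making the design matrix
numerically collinear (condition number > 1e10) are skipped and logged.
Degenerate branches are explicit: with SST ≈ 0 (constant target) nothing
enters; with SSE ≈ 0 (perfect fit) the 0/0 partial-F is replaced by a
coefficient-magnitude test at the scale of the data, which is what makes
noiseless parameter recovery exact. Tests verify fixed-pointness of the
returned set by exhaustive subset enumeration with statsmodels OLS as the
independent oracle.

**Random forest.** scikit-learn regression forest, 500 trees,
max_features = ⌈p/3⌉ (the regression convention), seeded. Predictions are
tree means, hence always inside the training-yield range.

**Metrics.** R² = 1 − Σ(x−x̂)²/Σ(x−x̄)², RMSE = √(Σ(x−x̂)²/n), and
MAPE = (Σ|x−x̂|/x̂)/n × 100. Two conventions here deserve a note. The
analysis this package reproduces prints its R² formula *without* the
"1 −" while describing higher-is-better behaviour; the standard 1 − SSE/SST
form is implemented, matching the interpretation rather than the typo. Its
MAPE formula puts the *predicted* value in the denominator (most texts use
the observed value); the printed form is the default and
`mape_denominator="observed"` switches to the conventional one.

**Leakage control.** Band/cell screening uses the training trial only; the
three trials have disjoint plot namespaces and the grid asserts it.

## The synthetic trial generator

The generator emulates the study design the pipeline was built for: 60-plot
trial-years, five nitrogen rates (0–400 kg·ha⁻¹) crossed with a small
variety panel, canopy spectra at four stages, yield in the 440–930 g·m⁻²
range.

Latent state per plot × stage: a fertility scalar
f = 0.20 + 0.80·N/(N+230) + variety offset (±0.06) + plot noise
(σ = 0.04), plus an *independent per-stage growth shock* (σ = 0.15)
representing weather/phenology variation. Chlorophyll, LAI and water proxies
are fixed stage-trajectory multiples of f (canopy peaks at heading/
flowering, senesces by milky). The shock term is what makes multi-stage
fusion genuinely informative: without it every stage is a deterministic
function of the same scalar and a single stage would carry all the signal.

Reflectance: a flat soil line (0.28) mixed with a canopy curve via
fractional cover 1 − e^{−0.55·LAI}. The canopy curve has pigment wells at
450 and 670 nm (depth saturating in chlorophyll; the red well is asymmetric
— 26 nm shoulder, 8 nm recovery — so that its recovery is complete before
the red edge and the planted edge position stays identifiable), a logistic
red edge with inflection 690 + 50·chl/(chl+0.9) nm and 9 nm slope width, an
LAI-saturating NIR plateau (0.50), a gentle SWIR roll-off, water wells at
1450/1940 nm, and additive sensor noise (σ = 0.004 reflectance, tripled
inside the 1350–1450 and 1800–1950 nm atmospheric water-vapour windows).

Yield: base 372 g·m⁻² + Σ_s w_s·g(chl_s, lai_s) + N(0, 40), with
g = 0.6(1−e^{−0.55·LAI}) + 0.4·chl/(chl+0.8) and stage weights
(95, 180, 165, 85) g·m⁻² — heading ≈ flowering dominant, mirroring the
agronomic finding that those stages predict yield best. The constants were
calibrated once so a 60-plot year reproduces the reference moments
(mean ≈ 686 g·m⁻², CV within the 0.11–0.21 band around 0.16) and so the
noiseless FD at 683 nm carries |r| > 0.5 against yield.

The second validation trial re-draws the *design* — two varieties with
wider spread, weaker fertility response (floor 0.14, gain 0.50, half-
saturation 300) — while leaving the latent→spectrum and latent→yield physics
untouched, so a well-specified model should transfer; its yield distribution
is KS-distinguishable from the base design in ≈100% of seed pairs.

**What the generator does not emulate**, and hence what passing tests do
not show about field data: radiative transfer (no PROSAIL-style leaf/canopy
physics), soil BRDF and row structure, illumination and atmospheric
variability beyond a fixed noise inflation, measurement-date effects, and
real varietal spectral signatures. Absolute model accuracies on this
benchmark (median held-out R² ≈ 0.74 for four-stage RF fusion) are
properties of the generator, not of any field dataset; only the *orderings*
— wavelet features ≥ derivative features, four-stage fusion ≫ best single
stage — are claimed, and the wavelet margin here is small (paired median
ΔR² ≈ +0.005) because Savitzky–Golay smoothing already removes most of the
synthetic sensor noise that wavelet features are robust to; field spectra
are far noisier, where the advantage is reported to be larger.

## Problem sizes and determinism

Default analyses use 60 plots × 4 stages × 2151 bands per trial, three
trials per benchmark, and 20 benchmark replicates for the directional
study — sizes chosen so the full test suite and the reproduction script
each run in minutes on a single core. Everything is driven by
`numpy.random.default_rng` with explicit seeds: the same seed gives
bit-identical trials, forests and reports, and the pipeline stamps every
report with a hash of its full configuration.

## Known limitations

* Tri-edge λ is grid-quantised (1 nm); no sub-band interpolation of the
  derivative maximum is attempted, so ±0.5 nm quantisation error is
  inherent.
* Wavelet screening at scales 2⁹–2¹⁰ reflects boundary extension as much as
  spectral shape (see above).
* The stepwise procedure tests one candidate at a time; with heavily
  collinear screened bands the retained set depends on column order (ties
  resolve toward earlier columns, i.e. lower wavelengths and stages earlier
  in the season).
* No multiple-testing correction is applied across the 2151 × 10 screening
  grid (by design, matching the emulated analysis); the significance bound
  is per-cell.
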