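# Methods

`skindrs` implements a diffuse-reflectance-spectroscopy (DRS) analysis of
psoriasis severity: skin reflectance measured at two source–detector
separations (SDS 1 and 2 mm) is inverted per wavelength to absorption and
reduced scattering coefficients, two physiological feature sets are derived
from the absorption spectrum, and a statistics layer relates those features
to instrument readings and clinician scores. A synthetic paired-site cohort
generator supplies fully controlled data so every stage is testable without
patient measurements.

## Forward models

**Monte Carlo transport (reference).** Weighted-photon random walk in a
semi-infinite homogeneous medium: pencil beam normally incident at the
origin, Henyey–Greenstein scattering with anisotropy `g = 0.9`
(`mu_s = mu_s' / (1 - g)`), Fresnel specular reflection at entry and
angle-dependent internal reflection at the boundary for a relative index
`n_rel = 1.4`, absorption by per-step weight attenuation `mu_a / mu_t`, and
Russian-roulette termination below weight 1e-4 with survival probability
1/10 (unbiased). Escaping weight is tallied in annular detectors 0.2 mm
wide centred on the probe separations (matching a 400 um collection fiber;
the fiber's numerical-aperture acceptance cone is *not* modelled — all exit
angles are accepted). The kernel is numba-compiled and bit-deterministic
for a fixed seed. Validation: the total diffuse reflectance of an
isotropically scattering matched-boundary half-space reproduces the
H-function plane-albedo benchmarks (omega = 0.9 -> 0.4157, omega = 0.8 ->
0.2860) within Monte Carlo noise, the energy balance
(specular + absorbed + escaped + roulette) closes to <= 1e-3, and the
standard error scales as 1/sqrt(n_photons).

**Diffusion dipole (fast oracle).** The fluence is the standard
extrapolated-boundary dipole (isotropic source at `z0 = 1/(mu_a + mu_s')`,
image across the extrapolated boundary `zb = 2 A D`). Detected reflectance
combines fluence and flux with radiance-weighted Fresnel collection
moments,

    R(rho) = C_phi * Phi(rho, 0) + C_j * j_z(rho, 0),

with `C_phi = 1/2 ∫ (1 - R_F(mu)) mu dmu ≈ 0.118` and
`C_j = 3/2 ∫ (1 - R_F(mu)) mu² dmu ≈ 0.306` for `n_rel = 1.4`; `A` is
computed from the first two Fresnel moments (≈ 2.95 at n = 1.4). The
flux-only dipole was tried first and deviates 10–23% from transport at
rho = 1–2 mm for skin-like media; the hybrid form stays within ~5%
(measured: −3.1% at 1 mm, −4.3% at 2 mm at `mu_a = 0.02`,
`mu_s' = 2 mm^-1`, 1e6 photons), which is why it is the package's closed
form.

## Inverse model

The forward map is sampled on a 20×20 log-spaced grid over
`mu_a ∈ [0.001, 1.5] mm^-1`, `mu_s' ∈ [0.3, 5] mm^-1` — chosen to bracket
published skin optical properties over 500–1380 nm including the hemoglobin
peaks of strongly erythematous lesions. Two interchangeable inverses operate
on `(log R1, log R2) -> (log mu_a, log mu_s')` (everything spans decades;
log coordinates make the map nearly linear):

* **lookup_interpolation** — C1 Clough–Tocher scattered interpolation with a
  nearest-neighbour fallback outside the training hull; fallback points are
  flagged `out_of_domain`, never silent.
* **learned_regressor** — a tanh feed-forward network, two hidden layers of
  32 units, trained by deterministic L-BFGS (a single 32-unit layer was
  tried first and missed the 5% round-trip contract; 32×32 is the smallest
  configuration that passes). Prediction is a plain numpy forward pass, so
  fitted models serialise to versioned JSON.

Both models recover off-grid media with ~1–2% median relative error and
agree with each other within ~3% median; inversion is strictly
per-wavelength with no spectral smoothing (smoothing would bias the PWFR).
Negative absorption predictions are clipped to zero and flagged (cannot
occur in log coordinates; kept as a contract).

## Spectral features

**Hemoglobin unmixing (500–600 nm).** Beer's-law decomposition
`mu_a(lambda) ≈ c_o2hb·eps_O2Hb + c_hhb·eps_HHb` by non-negative least
squares (concentrations are physical amounts; no offset or additional
chromophore — exactly the two named bases). Concentrations are in uM with
basis spectra in mm^-1 per uM (the ln 10 Beer's-law factor folded in);
`tHb = O2Hb + HHb` by construction.

**Pure-water fitting residual, PWFR (1230–1380 nm).** Scale-only fit
`mu_a(lambda) ≈ A · mu_a_water(lambda)` with the closed-form non-negative
scale `A = <w, m>/<w, w>`; the score is `100 × RSS / n_points`. A spectrum
exactly proportional to pure water scores 0 for any A ≥ 0; disturbance of
the first water absorption overtone by altered water–protein binding (a
compromised stratum-corneum barrier) raises the score. The fit deliberately
has no additive offset, and RSS (not the residual norm) is used; both
choices are isolated in one function. `compute_pwfr` is unit-preserving;
the pipeline reports PWFR on absorption expressed in cm^-1
(`extract_site_features` scales spectrum and water basis by 10), the
convention under which the score's clinical magnitudes (units to tens) are
defined — on a mm^-1 scale the same residuals would read 100× smaller.
Analysis windows are sampled at 2 nm (51 and 76 points), a
spectrometer-typical density.

## Chromophore basis

The bundled extinction/absorption tables are **synthetic** analytic
approximations (anchor points + shape-preserving log-space interpolation),
not literature data: O2Hb carries the 542/577 nm double peak, HHb the
556 nm single peak and ~10× stronger 660 nm absorption, water the visible
transparency window and the 1190/1450 nm bands. Magnitudes are
order-realistic so tens of uM hemoglobin and ~60% water give skin-like
absorption. Hemoglobin is set exactly to zero above 1150 nm (physically
negligible there), which makes the generator's water-band absorption an
exactly scaled water spectrum when the bound-water distortion vanishes.
All quantitative checks in the package are self-consistent with this basis;
none claims literature accuracy.

## Statistics layer

* Pearson r with the two-sided p from `t = r sqrt(n-2)/sqrt(1-r²)` on n−2
  df — identically the test of the fitted line against `y = constant` (the
  equivalence with the regression slope test is asserted to 1e-10).
* Fisher transformation `z = arctanh r`; two coefficients are compared with
  `z_stat = (z1 − z2)/sqrt(1/(n1−3) + 1/(n2−3))` (larger |z| first, so the
  one-tailed `p = 1 − Phi(z_stat)` is ≤ 0.5 and equals 0.5 for identical
  inputs). The standard-normal reference reproduces the three printed
  worked examples at n = 15 per group (0.86 vs 0.48 → 0.0296; 0.77 vs
  0.51 → 0.1312; |−0.78| vs |−0.68| → 0.2981); a Student-t reference does
  not. Negative pairs are compared by magnitude only under an explicit
  flag. The independent-samples standard error is used even though paired
  study designs share subjects; a dependent-correlations test is out of
  scope.
* Group tests are pooled-variance unpaired Student's t by default (a paired
  mode exists); degenerate zero-variance inputs resolve to p = 1 (equal
  means) or p = 0 (unequal), flagged.
* No multiple-testing adjustment anywhere; reports label p-values
  unadjusted.

## Synthetic cohort generator

The generator emulates a paired-design severity study: n = 15 subjects by
default, one lesion and one adjacent-uninvolved site each, 4 raters, 1%
multiplicative log-normal reflectance noise. Per site a latent severity
scalar couples clipped-Gaussian draws of the physiology fields (site-type
specific means/SDs; loadings make hemoglobin, scattering and the bound-water
distortion rise with severity while hydration falls). Absorption composes
as `c_o2hb·eps_O2Hb + c_hhb·eps_HHb + w(h)·mu_a_water + b·d(lambda)` with
dermal water fraction `w(h) = 0.55 + 0.25·h`, and `mu_s'(lambda) =
a·(lambda/500)^(−p)`.

The bound-water distortion `d` is a fixed two-lobe Gaussian shape
orthogonalised against the water spectrum on the 2 nm analysis grid and
normalised to unit rms there, so the scale-only water fit removes none of
it and the noiseless PWFR is exactly `10^4 · b²` on the cm^-1 reporting
scale — quadratic in the deviation amplitude and analytically checkable.
The negative lobe sits at 1365 nm where water absorption is strongest, so
composed absorption stays positive for all admissible amplitudes.

Instrument emulations (the vendor formulas are proprietary; these are
documented stand-ins, not reconstructions):

* **Erythema index**: `clamp(500·log10(R660/R568), 0, 999)` on reflectance
  from an effective probe sampling distance of 1.4 mm. Physics alone gives
  the index its selectivity: both hemoglobin species absorb equally near
  the 568 nm isosbestic region, but HHb's much stronger 660 nm absorption
  also depresses the numerator, largely cancelling its effect — the index
  tracks O2Hb more than HHb, with no engineered asymmetry.
* **Capacitance reading**: `120·h/(h + 0.5)` plus Gaussian noise, clamped
  at 0 — saturating and strictly increasing in hydration.
* **PASI subscores**: latent severities linear in physiology — erythema
  weighted 3:1 toward HHb (raters keying on the dusky colour of
  deoxygenated blood), desquamation proportional to the bound-water
  deviation, thickness driven by scattering amplitude and dryness — each
  discretised per rater to the 0–4 integer scale after additive noise and
  averaged over raters. These generative links are invented emulation; the
  study this package models reports correlations, not a generative model.

**Calibration.** Default parameters were set once so that large-cohort
(500-site) means of the *pipeline-computed* PWFR and the simulated
instrument readings land on the clinical summary constants the generator
emulates: lesion/uninvolved PWFR 7.44/2.90, erythema index 441.5/323.4,
capacitance 11.37/46.19. Measured at 500 sites the generator deviates at
most ~10% from these constants across seeds. The constants parameterise
the generator and calibration checks only; the package never claims to
reproduce clinical results — the patient data behind them are unavailable
by design.

## What the synthetic cohort does and does not show

Passing tests demonstrate internal consistency: the inversion recovers the
optics the generator produced, the features recover the physiology that
generated them, and the statistics reproduce the generator's correlation
structure (desquamation dominating PWFR, HHb dominating rated erythema,
the capacitance reading anticorrelating with severity scores). Real skin
is layered, contains melanin, collagen and lipids, has spatially
heterogeneous vasculature, and is measured through fiber probes with
NA-restricted collection — none of which the generator or the
semi-infinite homogeneous forward model represents. Agreement here
validates the pipeline's machinery, not its clinical accuracy.

## Numerical choices and degenerate inputs

* Problem sizes: study analyses run the diffusion-trained lookup inverse
  (seconds); the Monte Carlo cross-check uses 1e6 photons at one skin-like
  medium; power and structure checks use 100 seeds at n = 15 and 20 seeds
  at n = 200.
* Correlations with n < 3 or constant series are reported as undefined, not
  numbers; Fisher comparisons need n > 3 per group.
* Sites failing inversion are excluded with a logged reason; the subject's
  other site is retained for group tests.
* The PWFR window accepts a single wavelength (a one-point scale fit is
  exact); hemoglobin unmixing requires ≥ 3 points.
* Out-of-domain reflectance pairs fall back to the nearest training point
  and are flagged; flagged wavelengths are excluded from feature windows.
* Seeds: every stochastic component takes an explicit seed or Generator;
  cohort generation, Monte Carlo runs and regressor training are
  reproducible bit-for-bit under a fixed seed.

## Known limitations

Semi-infinite homogeneous medium (no epidermis/dermis stratification, no
melanin); no NA-restricted detection; independent-samples Fisher comparison
for what are really dependent correlations; the learned regressor's
fidelity is to the round-trip contract, not to any particular published
network; instrument emulations are qualitative stand-ins for proprietary
vendor algorithms.
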