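# Methods

## Digital calibration phantom

The phantom is a 380 × 380 × 50 mm PMMA slab discretized on the
256 × 256 / 2.21 mm acquisition grid (the footprint spans ~172 pixels).
Activity lives in three layers stacked along the depth axis: a *basal*
layer carrying a uniform background over the whole footprint, and
*layers 1–2* carrying the organ compartments (heart disc, two lung
rectangles, liver rectangle, thyroid disc; the mediastinum is a
background-only rectangle between the lungs). Compartments are
parameterized 2-D primitives: the published phantom's internal drawings
are not available, and the conversion-coefficient statistic depends
only on ROI means, not anatomical fidelity. Organ activity
concentrations are fixed ratios of the heart concentration (defaults:
liver 0.9, lung 0.3, thyroid 0.5); the background is the overall scale.

**Layer geometry.** Defaults are basal 10 mm, layer 1 10 mm, layer 2
30 mm, with the basal layer toward the anterior camera. This is a
deliberate departure from an equal-thirds split, forced by the
designated HMRs: with background confined to the basal layer and heart
activity confined to layers 1–2, requiring ideal anterior/posterior
HMRs of 2.6/3.5 reduces to a 2 × 2 linear system in the two heart-layer
activities, and a nonnegative solution exists only if the posterior/
anterior contrast ratio 2.5/1.6 is attainable, i.e. (centre-to-centre
distance between the basal and layer-1 layers) ≲ ln(2.5/1.6)/(2 μ_PMMA)
≈ 13 mm at 159 keV. Equal thirds (16.7 mm) is infeasible — the
calibration raises `CalibrationInfeasibleError` reporting the
attainable range, and the unit tests exercise exactly this case. The
default geometry yields heart areal activities of ≈16.9 (layer 1) and
≈3.0 (layer 2) for unit background concentration: the depth asymmetry
that makes the posterior HMR exceed the anterior one.

**Calibration.** `calibrate_activities` measures the ideal
(attenuation-only, blur-free, noise-free) ROI responses of three basis
phantoms (background + organs with heart zeroed; unit heart in layer 1;
unit heart in layer 2), solves the linear system exactly, and restores
the organ-to-heart concentration ratios. It is idempotent to machine
precision and reproduces the designated HMRs to well below the 10⁻⁴
contract.

## Collimator physics

Standard parallel-hole design theory, all lengths in mm:

* effective length `L_eff = L − 2/μ_Pb(E)`;
* geometric resolution `R_g = d (L_eff + b)/L_eff` at source distance `b`;
* geometric efficiency `g = (0.26 d² / (L_eff (d+t)))²` (hexagonal packing);
* minimal septal path `w_min = L t / (2d + t)`;
* penetration fraction `p(E) = exp(−μ_Pb(E) w_min)`.

Attenuation coefficients for lead, NaI(Tl) and PMMA come from an
embedded 12-point table (100–600 keV) taken from standard photon
cross-section compilations and interpolated log-log; the energy range
has no absorption edges, so the interpolation error is a few percent at
worst. The modelled ¹²³I spectrum is the 159 keV principal line
(abundance 0.833) plus the four lines above 400 keV (440.0, 505.3,
529.0, 538.5 keV; summed abundance ≈0.025). Low-energy X-rays are
omitted — they cannot reach the 159 keV ± 10% window.

The >1% penetration exclusion rule is defined on the analytic 159 keV
fraction. Note that several commercial low-energy designs (e.g. the
1.11/0.16/24.05 mm high-resolution type, minimal path 1.6 mm) exceed 1%
under this definition; the rule is meant for screening design grids,
not for validating commercial presets.

## Projection model

SIMIND-style stochastic transport is replaced by analytic expectation
images plus Poisson sampling. For each emission line `E` and view, the
expected image is the Beer–Lambert projection of the layer stack
(each layer attenuated through the material overlying its centre;
posterior view reverses depth order and mirrors left-right), convolved
with a two-component PSF and weighted by abundance × in-window
detection weight:

* **sharp core** — Gaussian with FWHM `√(R_g² + R_i²)` (geometric plus
  intrinsic), weight `g (1 − p)`;
* **penetration tail** — Gaussian with FWHM `max(10 R_g, 140 mm)`,
  weight `p (κ_ax g + κ_br)`.

The tail weight has two channels: photons that entered a hole aperture
and penetrated the adjacent septa (∝ `g p`, constant `κ_ax = 22.0`) and
wide-angle penetration through the septal slab (∝ `p`, constant
`κ_br = 0.0025`). A single channel cannot reproduce the published
low/low-middle/medium-energy coefficient spread: `p` alone ranks the
extended low-energy general-purpose design too close to the
high-resolution one, `g·p` alone too far. The two constants are *model
constants in the sense of a physics parameterization*: they were fixed
once, by least squares against the three published simulated
Discovery-series coefficients under noise-free projection, and then
frozen; no per-run or per-test fitting occurs. After freezing, the
compensated coefficients sit within ±0.05 of the published 0.55/0.70/0.88.

**Detection weights.** The 159 keV line uses full-energy efficiency
`1 − exp(−μ_NaI T)` times the in-window fraction of a Gaussian
photopeak whose FWHM scales as `0.098 √(140/E)·E`. Lines above the
window use a backscatter-downscatter path: transmission through the
crystal, 180° Compton backscatter in the material behind it
(`E' = E/(1 + 2E/511)` ≈ 162–173 keV — inside the window), re-detection
of the backscattered photon, its in-window fraction, and an albedo
constant (0.5, saturating mildly with backscatter-material thickness).
This path, rather than a weight proportional to crystal thickness, is
what gives the empirically observed *sign* of the crystal-thickness
effect: a 5/8-inch crystal gains ~14% photopeak efficiency while losing
~6% of the downscatter contamination, so low-energy coefficients rise
(0.513 → 0.538 in the bundled presets), matching the published
original-vs-standard detector table.

**Scatter.** In-phantom scatter of the photopeak line is a single broad
additive kernel (FWHM 60 mm) at fixed weight 0.1 of the sharp
component — a second-order effect for a 50 mm slab.

**Budget and noise.** Images are scaled so total expected counts equal
the photon budget times the spectrum-averaged in-window detection
weight, then Poisson-sampled with a seeded generator; identical seeds
give bit-identical images. Coefficients are count-ratio statistics, so
the absolute scale cancels. Default budgets are reduced from the
original 1.78 × 10⁹-photon runs: 10⁷ for validation-style runs (5
replicates) and 10⁶ per design for the grid campaign. At 10⁷ the
replicate SD of a compensated coefficient is ≈0.003; at 10⁶, ≈0.01 —
both small against every comparison band. Phantom-to-collimator
distance defaults to 50 mm for both views; the coefficients are
ratio-based and weakly sensitive to it.

## ROIs and statistics

The heart ROI is a circle at the heart-mask centroid with radius 0.8 ×
the inscribed radius; the mediastinal ROI is a 10 × 30 pixel rectangle
at the mediastinum centroid. Anchoring to the known compartment
centroids replaces the clinical auto-placement software, whose exact
geometry is not reproducible here; since the phantom geometry is
internal, this preserves the meaning of the statistic. Posterior-view
ROIs are the left-right mirror of the anterior set. The conversion
coefficient, the compensation line (slope 1.27, intercept −0.15,
applied by default because the multicenter experimental dataset needed
to refit it is not distributable) and the strict >1% exclusion follow
the published definitions; `fit_compensation` exists for users with
their own experimental pairs.

## Regression campaign

The design grid is the full cross-product of 8 hole diameters ×
12 septal thicknesses × 9 lengths = 864 candidates, of which 693 pass
the 1% penetration screen under this model (the original study
simulated an unidentified 283-design subset and retained 210; running
the full grid is reproducible where guessing the subset is not, at the
cost of different record counts). Retained designs are simulated once
at 10⁶ photons, split 3:2 into training/validation, and a squared-error
gradient-boosted regressor is grid-searched with fourfold CV over
learning rate {0.01, 0.05, 0.1, 0.2, 0.33, 0.5} × estimators
{5, 10, 25, 50, 100} × depth 1–8 — a discretization of the published
ranges containing the published tuned point. Permutation importances
use the validation split, 10 repeats, MSE scoring. On this dataset the
three-feature model attains the smallest validation RMSE of the seven
feature subsets (≈0.022, versus ≈0.067 for the OLS baseline), and
septal thickness dominates the importances. Unlike the published
ranking, hole diameter does not come second here — collimator length
does; the grid composition (which septa/length combinations survive
the penetration screen) differs from the original subset, and the
d-vs-L ordering is sensitive to it. Only the thickness-first ranking is
treated as a model property.

## Numerical choices and degenerate inputs

Gaussian convolutions use separable `scipy.ndimage` filters with
zero-padding boundaries (equivalent to 'same' convolution with a
normalized kernel). The penetration filter retains values exactly at
the threshold (strict `>` excludes). Calibration failure, transparent
collimators (μ·L ≤ 2), out-of-range energies, overlapping or
out-of-footprint compartments, ROIs leaving their masks, and zero
mediastinal means all raise typed errors with diagnostics. A photon
budget leaving fewer than 100 expected heart-region counts logs a
warning. All randomness flows through `numpy` `SeedSequence`-spawned
generators keyed by user seeds; every pipeline output carries the seed
and budget that produced it.

## What the synthetic data does and does not show

The generator reproduces the first-order mechanisms that make the
conversion coefficient collimator-dependent: energy-dependent septal
penetration, collimator blur, photopeak windowing, high-energy
downscatter, depth-dependent attenuation and Poisson statistics. It
does not model hole-array geometry, septal scatter, collimator X-ray
fluorescence, dead time or detector nonuniformity, and its penetration
tail is a calibrated two-constant parameterization rather than
transport physics. Passing tests therefore demonstrate that the
analysis chain and the regression protocol behave as published on data
with the right structure and magnitudes — not that the surrogate would
match a physical camera measurement outside the calibrated regime.
Absolute coefficients of high-penetration (>1% at 159 keV) low-energy
presets are over-degraded relative to real cameras and are not asserted
anywhere.
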