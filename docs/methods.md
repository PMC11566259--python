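# Methods

## Forward model

Time-resolved reflectance of a semi-infinite homogeneous diffusive medium is
evaluated with extrapolated boundary conditions as an image-source (dipole)
expansion: an isotropic source at depth z0 = 1/μs′ and its negative image
across the extrapolated boundary at −zb, with zb = 2·A·D. The diffusion
coefficient uses the modern absorption-independent convention D = 1/(3 μs′);
the legacy 1/(3(μa + μs′)) form changes the curve only at the percent level
for the parameter ranges covered here and was not needed. The boundary
parameter A(n) comes from the Groenhuis polynomial approximation of the
internal diffuse reflectance (A ≈ 3.25 at n = 1.4 against air), the
conventional choice for tissue/air interfaces; the literature offers several
A(n) parametrizations differing by a few percent in zb, which moves the
reflectance by far less than the Poisson noise of a 10^6-count DTOF. One
dipole is the default (`n_dipoles` is exposed); at ρ = 2.5 cm in reflectance
geometry higher-order images are numerically irrelevant.

Two analytic identities pin the implementation down and are enforced in the
tests: R(t; μa, μs′) = R(t; 0, μs′)·exp(−μa v t) holds at machine precision
by construction, and the time integral of R(t) equals the closed-form CW
reflectance of the same dipole (verified to < 0.1%, observed at ~1e-13
relative).

Units are cm and ps throughout; the vacuum speed of light is the CODATA
value, and v = c/n with a constant tissue refractive index n = 1.4.

## Discrete convolution and moments

Model curves are sampled on the instrument's channel grid (sample k sits at
t_offset + k·Δ, Δ = 9.7 ps by default). IRF convolution is a discrete linear
convolution with the IRF normalized to a unit-sum kernel, so the channel sum
is conserved and first moments add *exactly* (to float rounding); mean times
are therefore computed by channel summation rather than trapezoidal
quadrature, matching histogram semantics. No oversampling is applied: the
9.7 ps quantization of the synthetic data matches the quantization of the
model, so sub-channel interpolation would add complexity without accuracy.

## Fitting

The fit minimizes weighted least squares between the measured counts and the
amplitude-scaled convolved model inside a window from the first channel
reaching 80% of the peak on the rising edge to the last channel above 1% of
the peak on the tail — a common TD-NIRS windowing convention that keeps the
late, deep-probing photons while discarding the early rise where the
diffusion approximation is weakest. Both fractions are configurable and
recorded in the `FitReport`. On an IRF-convolved pulse at ρ = 2.5 cm this
window holds roughly 85% of the detected counts.

The amplitude is profiled analytically (closed-form optimal scale per
iteration), reducing the search to (log μa, log μs′); the log transform keeps
iterates positive without constraints. Poisson weighting uses variance
max(count, 1); uniform weighting is available for sensitivity checks.
Optimization is scipy's Levenberg–Marquardt with tolerances of 1e-10 and a
400-evaluation budget; non-convergence is reported through
`FitReport.converged`, never silently. A constant background (median of the
first 32 channels, configurable) is subtracted from both DTOF and IRF before
windowing, fitting and moment computation; the synthetic data are
background-free, so the default subtraction is a no-op there by design.

Noiseless on-manifold fits recover the generating (μa, μs′) to ~1e-6
relative over a 3x3 grid spanning the tabulated pediatric range; at 10^6
Poisson counts with a 60 ps FWHM IRF the bias is ≲ 0.1% and the SD ≈ 0.3–0.4%
per parameter (50 replicates).

## DPF

DPF = v·⟨t⟩/ρ. By default ⟨t⟩ is the *instrument-corrected measured* mean
time: the first moment of the background-subtracted DTOF minus the IRF
barycenter, using moment additivity of the convolution to undo the
instrumental broadening. The alternative mode evaluates the first moment of
the fitted model curve; on noiseless data the two agree to well under 3%.

### A known discrepancy in the reference values

The reference cohort tables are internally inconsistent between their
(μa, μs′) and DPF columns under this (standard) model: at the tabulated
optical properties the semi-infinite diffusion solution yields DPF ≈ 5.6–7.0,
while the tables print 3.8–5.2 — uniformly lower by almost exactly a factor
1/n. The published description of the DPF formula also mislabels v = c/n as
the speed of light *in vacuum*, which suggests an extra 1/n slipped into the
original processing chain. This package implements the formula as written
(v = c/n) and does not reproduce the printed DPF from the printed optical
properties. Consequently the synthetic generator treats the DPF columns as
*reported descriptors*, drawn directly from their cells, rather than deriving
them from the drawn (μa, μs′).

## Beer-law inversion and extinction data

Hemoglobin is treated as the only chromophore: a 2x2 linear solve of
ln(10)·ε·C = μa at (686, 830) nm. Negative concentration solutions are
returned with a `physical = False` flag, never clipped — they indicate model
misfit and must stay visible. The default extinction table uses the standard
compiled hemoglobin spectra (molar extinction 290/2150 at 686 nm and 974/693
cm⁻¹ M⁻¹ at 830 nm for HbO2/HHb). This choice is corroborated by the
reference tables themselves: Beer-transforming the tabulated hemoglobin cell
means reproduces the tabulated μa cells within their printed precision
(±0.005 cm⁻¹) in every cell. Water (Hale–Querry scale: 0.00465/0.0298 cm⁻¹)
and lipid (soybean-oil scale: 0.0006/0.005 cm⁻¹) spectra feed only the
contamination analysis. The whole table is swappable via a CSV file carrying
a source string.

The contamination error compares the hemoglobin-only inversion with a
corrected inversion in which `volume_fraction` x the pure chromophore's
absorption is first subtracted from each μa, and reports
100·(uncorrected − corrected)/corrected per quantity — a positive value means
the hemoglobin-only assumption overestimates. At the cohort-average μa,
90% water gives ≈ (−2, +21, +12, +8)% for (HHb, HbO2, tHb, SO2) and 90% lipid
stays within ±5% everywhere, reproducing the published error *magnitudes*;
the published signs follow the opposite (unstated) convention and are not
comparable directly.

## Cohort statistics

Age clusters are half-open two-year bins [lower, upper) partitioning [2, 18],
with the top cluster closed at 18 — the only partition-consistent reading of
overlapping labels like "2 to 4" / "4 to 6". Summaries use the sample (n−1)
SD (divisor configurable). Total rows are count-weighted means of cluster
means, which for a full partition equal the grand mean exactly before
rounding. Pearson correlations use the two-sided t-transform p-value, raw
(no multiplicity correction; Benjamini–Hochberg available but off by
default), with the standard strength classes on |r| (boundaries 0.3/0.5/0.7
belonging to the upper class). The repositioning coefficient of variation is
100·SD/mean over the five per-repositioning means (each the average of its
five acquisitions); computing it over all 25 DTOFs instead is exposed through
the same function by passing the raw values.

The DPF general equation is implemented as
DPF(A, λ) = α + β·A^γ + δλ³ + ελ² + ζλ with the published coefficients
(α = 223.3, β = 0.05624, γ = 0.8493, δ = −5.723e-7, ε = 0.001245,
ζ = −0.9025). Some printed renderings of this equation show two cubic λ
terms; that is a typesetting artifact — the cubic + quadratic + linear
polynomial above is the form in the originating reference and is what the
coefficient values require to produce physical DPF values (3–8 over ages
2–18 at 686/830 nm, verified in tests). The offset refit is closed-form:
α̂ = mean(observed − model-without-α), which can only decrease the mean
squared error.

## Synthetic cohort generator

The generator reproduces the reference study's structure: exact per-cell
counts (157 F / 148 M = 305 across 8 clusters), ages uniform within each
cluster, and per-cell truncated-normal draws at the tabulated mean ± SD for
auxology (BMI, BMI z-score, head circumference), physiology (HTC, Hb, HR,
BR, SpO2) and the measurement variables. Where a truncation bound is active
(only SpO2 ≤ 100% in practice) the location parameter is moment-matched so
the *truncated* law's mean equals the tabulated target — the tabulated means
are sample means of the bounded quantity.

Hemodynamics are parametrized by (tHb, SO2), drawn independently per
subject, with HbO2 = SO2·tHb and HHb = tHb − HbO2 derived. This choice is
data-driven: propagating the tabulated (tHb, SO2) SDs through these products
reproduces the tabulated HbO2/HHb SDs almost exactly (e.g. youngest female
cell: predicted 8.1/5.6 μM vs tabulated 8.2/5.5 μM), whereas independent
HbO2/HHb draws would inflate the derived SO2 spread well beyond its cells.
The absorption coefficients then follow from the forward Beer law, and μs′
is drawn from its cells — one subject can never carry mutually contradictory
optical and hemodynamic values. Because the μa cells are *derived*, they
match the tabulated μa only as well as the tables are self-consistent, which
is within printed precision (see above). Optional per-variable linear age
trends (centered on cluster midpoints, cell means preserved) can emulate the
reference cohort's qualitative correlations; they are off by default because
the tables specify only marginal summaries, not a joint distribution.

The protocol simulator draws, per probe replacement, one relative μa factor
and one relative μs′ factor applied at *both* wavelengths (a replaced probe
samples a slightly different tissue volume, shifting blood content and
scattering coherently across wavelengths) plus a per-wavelength coupling
(amplitude) factor; within a replacement, the five 1 Hz acquisitions differ
only by Poisson noise at 10^6 expected counts each. Defaults are 2.5% on μa,
2% on μs′ and 5% on amplitude. They were calibrated once, from the sampling
distribution of a five-sample CV, so that the interquartile per-subject CVs
of the fitted optical properties sit inside the published 1–5% band with
margin on both edges (a 5-sample CV at true σ scatters by ±35% around σ, so
a target near 2–2.5% centers the band). The wavelength-coherent μa
perturbation makes the HbO2/HHb repositioning errors common-mode, so SO2 —
a ratio — is far more precise (CV ≲ 0.2%) than tHb (~2%), reproducing the
qualitative hierarchy of the reference study. Amplitude variability is
absorbed by the fit's analytic amplitude profiling and by moment
normalization, as in the real analysis.

## What the synthetic data do and do not show

The generator emulates marginal cell statistics, protocol structure, photon
noise, and a plausible repositioning perturbation; it does not model layered
head anatomy, partial-volume effects, motion, ambient light, detector
afterpulsing, or the real covariance between auxological and optical
variables. Passing tests therefore demonstrate that the *pipeline* is
self-consistent and precise under its own assumptions — not that the clinical
precision figures are reproduced from real physics. The precision study is
explicitly a calibration property of generator + pipeline.

## Problem sizes and numerical choices

The default synthetic instrument uses 1024 channels x 9.7 ps (~10 ns), which
contains the DTOF to far below the 1%-of-peak tail at pediatric-head optical
properties; the file format and config support the full 4096-channel depth.
Studies run at: 3x3 noiseless grid; 50 Monte-Carlo replicates for recovery;
40 subjects x 2 wavelengths x 25 DTOFs (2000 fits) for precision; 20 seeds x
305 subjects for generator coverage. A single fit takes ~3 ms, so the whole
suite and the acceptance script each complete in well under a minute.

Degenerate inputs are rejected loudly: all-zero histograms (no fit window),
zero-area curves (no mean time), empty IRFs, zero tHb (SO2 is an explicit
`None`, never a silent 0), contamination exceeding measured absorption, and
constant inputs to the correlation.

## Known limitations

- Single homogeneous layer only; no two-layer or Monte-Carlo forward model.
- The DPF reported by the physics chain is ~n times the reference tables'
  DPF values (see the discrepancy note above); cross-study DPF comparisons
  must fix the v-convention first.
- The extinction table ships two wavelengths only; broadband fitting and
  additional chromophores (cytochrome oxidase, melanin) are out of scope.
- Reference Pearson r values between optical/hemodynamic variables and age
  are not reproduced numerically — they require the raw per-subject data,
  which only the optional age-trend hooks approximate qualitatively.
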