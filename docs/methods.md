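# Methods

This note records the models implemented in bilayerlab, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
generator does and does not emulate.

## SANS: thin-sheet Kratky–Porod analysis

**Model.** For dilute unilamellar vesicles (structure factor S(q) ≈ 1,
valid for extruded dispersions below ~2 wt% lipid) whose radius is large
compared with 1/q, the coherent intensity in the Guinier regime follows
the thin-sheet form I(q) = C exp(−q²Rg²)/q², where Rg is the
one-dimensional radius of gyration of the bilayer scattering-length
profile. The sheet thickness follows from d_g² = 12 Rg², exact for a
uniform slab and a good approximation for real bilayers when no solvent
penetrates the headgroup region.

**Procedure.** (1) The flat incoherent background is the mean intensity
over a high-q tail window (default 4–5 nm⁻¹, ≥ 5 points) where the
coherent term has decayed to ~10⁻⁸ of its low-q level; the subtracted
constant is recorded in the curve metadata. For a curve with zero true
background the procedure subtracts the (tiny) model tail — a documented
small bias, quantified in the tests. (2) Ordinary least squares of
ln(I q²) on q² over the fit window (default 0.31–1.14 nm⁻¹, ≥ 6 points);
Rg = √(−slope), d_g = √12·Rg. Points with I ≤ 0 inside the window abort
the fit — silent dropping would bias the slope toward shallower values.
A σ-weighted fit is available but not default (the field protocol is the
unweighted plot).

**Uncertainties.** d_g_sd propagates the slope standard deviation only
(background-subtraction uncertainty is not propagated). When the curve
carries per-point σ, the slope variance is computed by exact propagation
of var(ln I q²) = (σ/I)² through the least-squares estimator; counting
noise is strongly heteroscedastic in log space across the window (×8
between its ends), and a residual-based OLS error would understate the
slope uncertainty (Monte-Carlo coverage of ±2 SD intervals drops to
~80 % instead of ~95 %). Without per-point σ the residual-based estimate
is used.

**Diagnostics.** r² (squared Pearson correlation) below 0.993 flags the
result as non-conforming without failing it. `guinier_validity` reports
max(q)·Rg over the window: for a ~3.9 nm bilayer the standard window
reaches q·Rg ≈ 1.28, beyond the q·Rg < 1 validity limit. The package
reports this tension rather than resolving it; the slab-oracle tests
quantify the consequence (a uniform slab fitted over the full window
appears ~12 % too thick, while windows restricted to q·Rg ≤ 0.5 recover
the thickness within 2 %). For the Guinier-form generator the recovery is
exact by construction at any window.

## SAXS/WAXS: lamellar period and crystalline drug

Diffraction orders of the lamellar phase sit at q_n = 2πn/d. Each order
is fitted with a Lorentzian plus a local linear background in a window of
± 5 half-width guesses around the expected center — a local per-peak fit
rather than a global multi-peak fit, which is robust to the diffuse
scattering between orders of a fluctuating, weakly-ordered stack.
Initial centers come from a Savitzky–Golay-smoothed peak picker (an
`init_d` guess overrides); subsequent orders are searched at multiples of
the fitted first-order center. d = 2π/q₁ exactly;
d_sd = 2π·center_sd/q₁²; the order ratio q₂/q₁ (2.000 for an ideal
lamellar stack) is reported as a lattice diagnostic. The water layer is
d_W = d − d_L with d_L taken from the SANS thickness.

The WAXS window (default 10–18 nm⁻¹) is fitted with one broad Lorentzian
plus linear background in two passes (points beyond 3 robust SD masked on
the second) so sharp peaks do not bias the band. Sharp crystalline
reflections are detected as positive residual excursions above 4 robust
SD (with a small absolute floor so featureless noise-free curves detect
nothing), and kept when narrower than 0.2 × the broad half-width.
Neighbouring reflections closer than their widths (e.g. a 14.8/14.9 nm⁻¹
pair) may merge into one residual excursion; peaks sharing an excursion
are flagged `shares_run` and the result carries a `partially_resolved`
note instead of silently reporting a merged position.

## DSC: transition parameters

Baseline correction subtracts the straight line through the
(mean T, mean cp) points of two flanking windows (defaults 2–8 and
36–40 °C, ≥ 5 points each). Because that line passes through the window
means by construction, window overlap with the transition is detected on
half-window mean residuals instead (raised when they exceed 3× the point
noise *and* 5 % of the peak height) — windows brushing a broad peak's
final percent of tail pass with a documented <2 % enthalpy bias, windows
covering the peak raise. A sigmoidal baseline is deliberately not
implemented; the linear two-point form is the stated default and the
output records it as an assumption.

Tm is the temperature of the maximum of a local-quadratic
(Savitzky–Golay, 11-point default) smoothed curve with sub-grid parabolic
refinement — the transition of a complex lipid mixture is broad and
low-cooperativity, so a raw argmax would be noise-limited. ΔH is the
trapezoidal integral of the raw corrected curve (smoothing would bias the
area); FWHM is the half-height width of the smoothed curve with crossings
located by linear interpolation, leftmost pair on ties. Replicate
heating scans are combined as per-parameter mean and SD; mixing heating
and cooling scans is an error.

## The endotherm generator shape

The generated endotherm is a skew-normal peak reparameterised so that its
numerical mode equals Tm and its numerical FWHM equals the requested
width exactly, multiplied by a cosine "completion taper" that brings the
excess heat capacity smoothly to zero over a span of 0.25 × FWHM beyond
each half-maximum point, and renormalised numerically so its trapezoidal
area on the output grid equals ΔH exactly. The taper encodes a physical
fact about real scans: the transition completes within the measured
range, so the excess heat capacity is indistinguishable from baseline in
the flanking windows. An untapered Gaussian-tailed peak of FWHM 12.5 °C
centred at 28.1 °C cannot satisfy that — it necessarily leaves several
percent of its area inside 2–8 / 36–40 °C windows (no pair of Gaussian
flank widths can sum to the required FWHM while decaying below 0.1 % of
peak height at both windows), which would make the stated enthalpy
unrecoverable by any baseline procedure. At zero asymmetry the shape
inside its half-max region is an exact Gaussian (σ = FWHM/2.3548) up to
the uniform renormalisation. The default asymmetry −3 gives the gradual
low-temperature shoulder and steep completion typical of multicomponent
lipid endotherms. Grids that truncate the tapered peak by more than
0.5 % of its area are rejected.

## Excimer fluorescence

η = mean(excimer trace)/mean(monomer trace) — the ratio of time-averaged
intensities, not the average of per-sample ratios, matching how the
time-based measurement is reduced. η_sd is delta-method propagation of
the two standard errors of the mean (SEM-based; the output records this
basis, since "standard deviation of the intensities" is ambiguous between
SD and SEM). Traces must carry ≥ 10 samples and, when wavelength
metadata is present, match 376 ± 5 nm (monomer) and 480 ± 5 nm (excimer)
to catch swapped inputs. Spectrum normalisation scales so the local
maximum within 376 ± 3 nm equals 100 (tolerant to small calibration
offsets).

The generator builds the emission spectrum from five narrow Gaussian
monomer vibronic bands (band I at 376 nm; bands II–V at fixed offsets
with decreasing heights, widths 2.2 nm — only band I carries quantitative
meaning) plus a broad 32 nm-wide excimer band at 480 nm whose height is
solved, including the small band overlaps, so that I(480)/I(376) equals
η exactly. Time traces are Gaussian with relative noise about means
(monomer_mean, η·monomer_mean).

## Synthetic-data generator: scope and defaults

Defaults reproduce the studied drug-free surfactant at the measurement
conditions: SANS on q = 0.05–5 nm⁻¹ (256 points) with thickness 3.88 nm,
Δλ/λ = 0.10 and 2 % counting noise; SAXS/WAXS on 0.1–18 nm⁻¹ (0.01
spacing) with d = 7.8 nm, two orders, broad chain band at 14 nm⁻¹; DSC on
2–40 °C (0.05 °C steps) with (28.1 °C, 18 J/g, 12.5 °C); fluorescence
traces of 120 s at 0.5 s sampling with η = 1.13 (Pyr10PC) or 1.87
(Pyr4PC) and 2 % relative noise. The vesicle radius default (39.5 nm)
matches the extruded-vesicle size; the thin-sheet analysis is insensitive
to it over the fitted window.

Instrument effects modelled: Gaussian resolution smearing in q with
σ_q = q·(Δλ/λ)/2.355 (the FWHM-like velocity-selector spread, evaluated
by 21-point Gauss–Hermite quadrature; zero spread is the identity), and
Gaussian counting noise with σ = noise_level·√I for scattering, absolute
σ for DSC, relative σ for fluorescence. Equal seeds give bit-identical
data (`numpy.random.default_rng`).

Not modelled — and therefore not demonstrated by passing tests: vesicle
polydispersity and multilamellar contamination in SANS; Caillé/
paracrystalline lineshapes, 2D detector effects and absolute intensity
calibration in SAXS (intensities are in relative units throughout);
scan-rate kinetics and sub-transition deconvolution in DSC; fluorescence
lifetime effects, inner-filter and spectral-response corrections.
Parameter recovery on these synthetic data validates the estimators under
the stated noise models, not the instrument data reduction that precedes
them in a real experiment.

## Composition arithmetic

r = (100/M_lipid)/(wt%/M_drug) lipids per drug molecule, with
M_lipid = 762 g/mol (average for the surfactant mixture) and
M_drug = 430.53 g/mol (budesonide) built in and overridable: 4 wt% →
1:14, 8 wt% → 1:7. Note an internal inconsistency in the source values
this package is pointed at: a loading quoted as "0.05 wt% (~1:100
mol/mol)" does not verify — 0.05 wt% gives ≈ 1:1130 while 0.5 wt% gives
≈ 1:113 ≈ 1:100. The package computes the ratio for whatever loading it
is given and does not guess which figure was intended; both conversions
are pinned in the tests.

## Problem sizes and determinism

All analyses are closed-form or small local nonlinear fits; the full test
suite (including 100-seed Monte-Carlo coverage checks for d_g and η)
runs in a few seconds on one CPU, and `scripts/acceptance.py` in under a
second. Monte-Carlo sample sizes (100 seeds for coverage, 300 for
unbiasedness, 20 for noisy SAXS recovery, 8-seed amplitude sweeps for
WAXS detection rates) were chosen as the smallest sizes at which the
binomial/SEM bounds asserted are meaningful. Pipeline runs with the same
config and seed produce byte-identical JSON records.
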