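# bilayerlab

Quantitative analysis of drug–lung-surfactant systems from four standard
biophysical measurements, built as a reusable, tested pipeline with a
synthetic-data generator so that every analysis stage is verifiable by
parameter recovery.

Clinical lung surfactants (porcine extracts such as Curosurf®) are being
explored as carriers for hydrophobic drugs like the corticosteroid
budesonide. Assessing how the drug perturbs the carrier requires extracting
a small set of structural and thermodynamic parameters from routine
measurements:

| measurement | quantity | model |
|---|---|---|
| SANS (unilamellar vesicles) | bilayer thickness *d*<sub>g</sub> | Kratky–Porod: ln(*I q*²) vs *q*² linear with slope −*R*<sub>g</sub>², *d*<sub>g</sub> = √12 *R*<sub>g</sub> |
| SAXS (multilamellar vesicles) | lamellar repeat distance *d* | Lorentzian orders at *q*<sub>n</sub> = 2π*n*/*d* over linear background; *d* = 2π/*q*₁ |
| WAXS | chain packing / crystalline drug | broad band at ~14 nm⁻¹ + sharp residual peaks |
| DSC | *T*<sub>m</sub>, Δ*H*, FWHM of the gel→fluid transition | linear baseline, peak maximum, trapezoidal area |
| pyrene excimer fluorescence | lateral-pressure parameter η | η = ⟨*I*₄₈₀⟩/⟨*I*₃₇₆⟩ from time traces |

The thin-sheet SANS intensity in the Guinier regime (*q R*<sub>g</sub> < 1) is

    I(q) = C exp(−q² Rg²) / q² + B,

with *B* the flat incoherent background subtracted from a high-*q* tail
window; the repeat distance decomposes as *d* = *d*<sub>L</sub> + *d*<sub>W</sub>
(bilayer + water layer). Composition arithmetic converts drug weight
percent to lipid-per-drug mole ratios (MW 762 g/mol for the surfactant,
430.53 g/mol for budesonide).

Each modality follows the statsmodels pattern — a model object built from a
data container whose `fit()` returns a results object with estimates,
uncertainties and a `summary()`:

* `KratkyPorod(curve).fit()` → `KratkyPorodResult` (with `guinier_validity`
  diagnostic),
* `LamellarModel(curve).fit()` → `LamellarResult`,
  `WaxsModel(curve).fit()` → `WaxsResult`,
* `TransitionModel(thermogram).fit()` → `ThermogramResult`
  (+ `average_scans`),
* `LateralPressure(excimer, monomer).fit()` → `LateralPressureResult`.

`bilayerlab.synthetic` generates all four kinds of data with known ground
truth, seeded noise and (for SANS) Gaussian wavelength-spread smearing;
`bilayerlab.pipeline` orchestrates simulate → analyze → report runs from a
YAML config.

## Worked example

```python
import bilayerlab as bl

# synthetic SANS curve of a 3.88 nm bilayer with 2 % counting noise
params = bl.SansModelParams(thickness_true=3.88, background_B=0.05,
                            wavelength_spread=0.0, noise_level=0.02, seed=42)
curve = bl.gen_sans_curve(params)
curve = bl.subtract_incoherent_background(curve, tail_window=(4.0, 5.0))
result = bl.KratkyPorod(curve, q_window=(0.31, 1.14)).fit()
print(result.summary())
```

```
Kratky-Porod thin-sheet fit
---------------------------
q window        : 0.310-1.140 nm^-1  (43 points)
slope           : -1.26249 +/- 0.01639 nm^2
r^2             : 0.99834
Rg              : 1.1236 +/- 0.0073 nm
d_g = sqrt(12)Rg: 3.8923 +/- 0.0253 nm
max(q)*Rg       : 1.278  [beyond Guinier regime]
```

The fit recovers the ground-truth thickness (3.8923 ± 0.0253 nm vs 3.88 nm
generated) with the slope uncertainty propagated into *d*<sub>g</sub>; the
last line reports that the standard 0.31–1.14 nm⁻¹ window reaches
*q R*<sub>g</sub> ≈ 1.28, beyond the strict Guinier validity limit — a
known property of this protocol that the diagnostic surfaces rather than
hides. The same pattern runs for DSC:

```python
tg = bl.gen_thermogram(bl.EndothermParams(noise_level=0.01, seed=42))
res = bl.TransitionModel(tg, pre_window=(2, 8), post_window=(36, 40)).fit()
print(res.summary())
```

```
DSC transition parameters
-------------------------
Tm   : 28.28 degC (maximum of smoothed peak)
dH   : 18.01 J/g (trapezoidal area)
FWHM : 12.50 degC
baseline: intercept 0.04934, slope 0.001996 J/g/degC per degC
```

recovering the generated (28.1 °C, 18.0 J/g, 12.5 °C) transition from a
noisy scan, along with the injected linear baseline.

The same analyses are available from the shell:

```sh
bilayerlab simulate --kind sans --out curve.dat --thickness 3.88 --seed 1
bilayerlab analyze-sans curve.dat --q-min 0.31 --q-max 1.14
bilayerlab run config.yaml          # full simulate -> analyze -> report
```

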