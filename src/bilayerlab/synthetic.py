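"""Synthetic measurement generator with known ground truth.

Every analysis stage in this package is validated by parameter recovery:
curves are generated from closed-form models with known parameters,
instrument effects (wavelength-spread smearing, counting noise) are applied
on top, and the analysis must return the inputs. The generators emulate

* SANS curves of unilamellar vesicles over q = 0.05-5 nm^-1 — a thin-sheet
  Guinier form ``C exp(-q^2 Rg^2)/q^2``, a uniform-slab form factor, or a
  core-shell (hollow sphere) vesicle, each over a flat incoherent
  background, optionally smeared by a Gaussian wavelength spread;
* SAXS lamellar patterns — Lorentzian diffraction orders at q_n = 2 pi n/d
  on a linear diffuse background, together with the broad WAXS acyl-chain
  band near 14 nm^-1 and optional sharp crystalline drug peaks;
* DSC endotherms — a skew-normal peak with exact mode (Tm), full width at
  half maximum and area (transition enthalpy), brought smoothly to zero a
  fixed span beyond its half-maximum points, as a real gel-to-fluid
  transition completes within the scanned range;
* pyrene monomer/excimer emission — five narrow monomer vibronic bands
  (band I at 376 nm) plus the broad unstructured excimer band at 480 nm,
  scaled so the 480/376 intensity ratio equals the lateral-pressure
  parameter eta, and the matching fixed-wavelength time traces.

All randomness is driven by an explicit integer ``seed`` through
``numpy.random.default_rng``; equal seeds give bit-identical data. Counting
noise is Gaussian with standard deviation ``noise_level * sqrt(I)`` for
scattering curves (a counting-statistics surrogate), absolute for DSC, and
relative to the trace mean for fluorescence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import skewnorm

from .data import EmissionSpectrum, ScatteringCurve, Thermogram, TimeTrace

__all__ = [
    "SansModelParams", "LamellarModelParams", "EndothermParams",
    "FluorescenceParams",
    "gen_sans_curve", "gen_saxs_waxs_pattern", "gen_thermogram",
    "gen_fluorescence",
    "guinier_sheet_intensity", "uniform_slab_intensity",
    "core_shell_vesicle_intensity", "smear_wavelength_spread",
]

SQRT12 = float(np.sqrt(12.0))
#: FWHM of a unit-variance Gaussian; converts between FWHM and sigma.
GAUSS_FWHM = float(2.0 * np.sqrt(2.0 * np.log(2.0)))


def _default_sans_q() -> np.ndarray:
    # instrument q-domain 0.05-5 nm^-1
    return np.linspace(0.05, 5.0, 256)


def _default_saxs_q() -> np.ndarray:
    # one pattern covering the lamellar (SAXS) and chain-packing (WAXS) regions
    return np.arange(0.10, 18.0, 0.01)


def _default_dsc_T() -> np.ndarray:
    # DSC scan range 2-40 degC at 1 degC/min; 0.05 degC sampling
    return np.arange(2.0, 40.0 + 1e-9, 0.05)


# --------------------------------------------------------------------------
# SANS

@dataclass
class SansModelParams:
    """Ground truth for a synthetic SANS curve of bilayer vesicles.

    ``thickness_true`` is the bilayer thickness in nm; for the
    ``guinier_sheet`` model it maps onto the thin-sheet radius of gyration
    as Rg = thickness/sqrt(12). ``scale_C`` and ``background_B`` are the
    forward-scale constant and the flat incoherent level in relative units.
    ``wavelength_spread`` is the velocity-selector Delta-lambda/lambda
    (FWHM-like, 0.10 for the emulated instrument). The interparticle
    structure factor is taken as 1 (dilute extruded vesicles).
    """

    model_kind: str = "guinier_sheet"
    thickness_true: float = 3.88
    scale_C: float = 1.0
    background_B: float = 0.05
    vesicle_radius: float = 39.5
    wavelength_spread: float = 0.10
    q_grid: np.ndarray = field(default_factory=_default_sans_q)
    noise_level: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.model_kind not in (
                "guinier_sheet", "uniform_slab", "core_shell_vesicle"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.thickness_true <= 0:
            raise ValueError("thickness_true must be > 0")
        if self.scale_C <= 0:
            raise ValueError("scale_C must be > 0")
        if self.background_B < 0:
            raise ValueError("background_B must be >= 0")
        if self.wavelength_spread < 0:
            raise ValueError("wavelength_spread must be >= 0")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        self.q_grid = np.asarray(self.q_grid, dtype=float)
        if np.any(self.q_grid <= 0):
            raise ValueError("q_grid must be strictly positive "
                             "(the model divides by q^2)")
        if np.any(np.diff(self.q_grid) <= 0):
            raise ValueError("q_grid must be strictly increasing")
        if self.model_kind == "core_shell_vesicle":
            if self.vesicle_radius <= self.thickness_true / 2:
                raise ValueError("vesicle_radius must exceed half the "
                                 "bilayer thickness")


def guinier_sheet_intensity(q, thickness: float, scale_C: float = 1.0):
    """Thin-sheet Guinier intensity C exp(-q^2 Rg^2)/q^2, Rg = t/sqrt(12)."""
    q = np.asarray(q, dtype=float)
    rg2 = thickness * thickness / 12.0
    return scale_C * np.exp(-q * q * rg2) / (q * q)


def uniform_slab_intensity(q, thickness: float, scale_C: float = 1.0):
    """Thin-sheet intensity of a uniform slab of the given thickness.

    The slab thickness profile has the Fourier transform
    L sinc(qL/2); the planar-sheet intensity is its square divided by q^2,
    normalised so the q -> 0 limit matches ``scale_C / q^2``.
    """
    q = np.asarray(q, dtype=float)
    x = q * thickness / 2.0
    return scale_C * (np.sinc(x / np.pi)) ** 2 / (q * q)


def _sphere_amplitude(qr: np.ndarray) -> np.ndarray:
    """3 (sin x - x cos x)/x^3, the normalised homogeneous-sphere amplitude."""
    out = np.empty_like(qr)
    small = np.abs(qr) < 1e-4
    x = qr[~small]
    out[~small] = 3.0 * (np.sin(x) - x * np.cos(x)) / x ** 3
    out[small] = 1.0 - qr[small] ** 2 / 10.0
    return out


def core_shell_vesicle_intensity(q, thickness: float, radius: float,
                                 scale_C: float = 1.0):
    """Hollow-sphere (single-shell vesicle) form factor intensity.

    ``radius`` is the mid-bilayer vesicle radius in nm; the shell spans
    radius +/- thickness/2. Normalised to scale_C at q -> 0.
    """
    q = np.asarray(q, dtype=float)
    r_out = radius + thickness / 2.0
    r_in = radius - thickness / 2.0
    v_out = r_out ** 3
    v_in = r_in ** 3
    amp = (v_out * _sphere_amplitude(q * r_out)
           - v_in * _sphere_amplitude(q * r_in)) / (v_out - v_in)
    return scale_C * amp ** 2


# Gauss-Hermite nodes for resolution smearing (probabilists' convention).
_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(21)
_GH_WEIGHTS = _GH_WEIGHTS / np.sqrt(2.0 * np.pi)


def smear_wavelength_spread(model: Callable[[np.ndarray], np.ndarray],
                            q: np.ndarray, spread: float) -> np.ndarray:
    """Smear a model curve by the wavelength-spread resolution function.

    The spread is treated as an FWHM-like relative width, giving a Gaussian
    resolution kernel in q of width sigma_q = q * spread / 2.355 evaluated
    by 21-point Gauss-Hermite quadrature. ``spread = 0`` is the identity.
    """
    q = np.asarray(q, dtype=float)
    if spread == 0:
        return model(q)
    sigma = q * spread / GAUSS_FWHM
    qq = q[:, None] + sigma[:, None] * _GH_NODES[None, :]
    qq = np.clip(qq, 1e-9, None)
    return model(qq) @ _GH_WEIGHTS


def _sans_model(params: SansModelParams) -> Callable[[np.ndarray], np.ndarray]:
    kind = params.model_kind
    if kind == "guinier_sheet":
        return lambda q: guinier_sheet_intensity(
            q, params.thickness_true, params.scale_C)
    if kind == "uniform_slab":
        return lambda q: uniform_slab_intensity(
            q, params.thickness_true, params.scale_C)
    return lambda q: core_shell_vesicle_intensity(
        q, params.thickness_true, params.vesicle_radius, params.scale_C)


def gen_sans_curve(params: SansModelParams) -> ScatteringCurve:
    """Generate a synthetic SANS curve with seeded counting noise.

    The noiseless, unsmeared curve equals the chosen closed-form model plus
    the flat incoherent background pointwise. Noise is zero-mean Gaussian
    with standard deviation ``noise_level * sqrt(I_model)``, recorded as the
    per-point ``sigma`` of the returned curve.
    """
    q = params.q_grid
    model = _sans_model(params)
    I_coh = smear_wavelength_spread(model, q, params.wavelength_spread)
    I = I_coh + params.background_B
    sigma = None
    if params.noise_level > 0:
        sigma = params.noise_level * np.sqrt(np.clip(I, 0.0, None))
        rng = np.random.default_rng(params.seed)
        I = I + rng.normal(0.0, 1.0, size=len(q)) * sigma
    meta = {
        "modality": "SANS",
        "model_kind": params.model_kind,
        "temperature_C": 40.0,
        "wavelength_spread": params.wavelength_spread,
        "seed": params.seed,
    }
    return ScatteringCurve(q, I, sigma, meta)


# --------------------------------------------------------------------------
# SAXS / WAXS

@dataclass
class LamellarModelParams:
    """Ground truth for a lamellar SAXS pattern with a WAXS chain band.

    Diffraction orders sit at q_n = 2 pi n / d_true with Lorentzian
    half-widths ``peak_widths`` (HWHM, nm^-1) and peak heights
    ``peak_amplitudes`` over the linear diffuse background
    ``bg_intercept + bg_slope * q``. The WAXS region carries one broad
    liquid-chain band at ``waxs_broad_center`` (default 14 nm^-1) plus any
    sharp ``crystalline_peaks`` given as (center, HWHM, height) triples.
    """

    d_true: float = 7.8
    n_orders: int = 2
    peak_widths: Sequence[float] = (0.035, 0.05)
    peak_amplitudes: Sequence[float] = (1.0, 0.25)
    bg_intercept: float = 0.05
    bg_slope: float = -0.002
    waxs_broad_center: float = 14.0
    waxs_broad_width: float = 1.2
    waxs_broad_amplitude: float = 0.3
    crystalline_peaks: List[Tuple[float, float, float]] = field(
        default_factory=list)
    q_grid: np.ndarray = field(default_factory=_default_saxs_q)
    noise_level: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.d_true <= 0:
            raise ValueError("d_true must be > 0")
        if self.n_orders < 1:
            raise ValueError("n_orders must be >= 1")
        self.peak_widths = list(self.peak_widths)[: self.n_orders]
        self.peak_amplitudes = list(self.peak_amplitudes)[: self.n_orders]
        while len(self.peak_widths) < self.n_orders:
            self.peak_widths.append(self.peak_widths[-1])
        while len(self.peak_amplitudes) < self.n_orders:
            self.peak_amplitudes.append(self.peak_amplitudes[-1] / 4.0)
        if any(w <= 0 for w in self.peak_widths):
            raise ValueError("peak widths must be > 0")
        if self.waxs_broad_width <= 0:
            raise ValueError("waxs_broad_width must be > 0")
        seen = set()
        for center, width, _amp in self.crystalline_peaks:
            if width <= 0:
                raise ValueError("crystalline peak widths must be > 0")
            if center in seen:
                raise ValueError(
                    f"duplicate crystalline peak center {center}")
            seen.add(center)
        self.q_grid = np.asarray(self.q_grid, dtype=float)
        if np.any(np.diff(self.q_grid) <= 0) or np.any(self.q_grid <= 0):
            raise ValueError("q_grid must be positive and strictly increasing")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")


def _lorentzian(q, center, hwhm, height):
    return height * hwhm ** 2 / ((q - center) ** 2 + hwhm ** 2)


def lamellar_pattern_model(params: LamellarModelParams,
                           q: Optional[np.ndarray] = None) -> np.ndarray:
    """Noise-free SAXS/WAXS pattern for the given ground truth."""
    if q is None:
        q = params.q_grid
    q = np.asarray(q, dtype=float)
    I = params.bg_intercept + params.bg_slope * q
    for n in range(1, params.n_orders + 1):
        center = 2.0 * np.pi * n / params.d_true
        I = I + _lorentzian(q, center, params.peak_widths[n - 1],
                            params.peak_amplitudes[n - 1])
    I = I + _lorentzian(q, params.waxs_broad_center,
                        params.waxs_broad_width,
                        params.waxs_broad_amplitude)
    for center, hwhm, height in params.crystalline_peaks:
        I = I + _lorentzian(q, center, hwhm, height)
    return np.clip(I, 0.0, None)


def gen_saxs_waxs_pattern(params: LamellarModelParams) -> ScatteringCurve:
    """Generate a lamellar SAXS pattern plus WAXS band with seeded noise."""
    q = params.q_grid
    I = lamellar_pattern_model(params)
    sigma = None
    if params.noise_level > 0:
        sigma = params.noise_level * np.sqrt(I)
        rng = np.random.default_rng(params.seed)
        I = I + rng.normal(0.0, 1.0, size=len(q)) * sigma
    meta = {
        "modality": "SAXS/WAXS",
        "temperature_C": 40.0,
        "seed": params.seed,
        "n_orders_true": params.n_orders,
    }
    return ScatteringCurve(q, I, sigma, meta)


# --------------------------------------------------------------------------
# DSC

@dataclass
class EndothermParams:
    """Ground truth for a synthetic DSC endotherm.

    The peak is a skew-normal of shape ``asymmetry`` reparameterised so that
    its numerical mode is exactly ``Tm_true`` and its full width at half
    maximum exactly ``fwhm_true``; a cosine taper spanning
    ``completion_span * fwhm_true`` beyond each half-maximum point brings
    the excess heat capacity smoothly to the baseline (transitions of real
    lipid mixtures complete within the scanned range), and the tapered peak
    is renormalised so its trapezoidal area on ``T_grid`` is exactly
    ``dH_true``. ``asymmetry < 0`` gives the gradual low-temperature
    shoulder and steep completion typical of multicomponent endotherms.
    """

    Tm_true: float = 28.1
    dH_true: float = 18.0
    fwhm_true: float = 12.5
    asymmetry: float = -3.0
    completion_span: float = 0.25
    baseline_intercept: float = 0.05
    baseline_slope: float = 0.002
    T_grid: np.ndarray = field(default_factory=_default_dsc_T)
    noise_level: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.dH_true <= 0:
            raise ValueError("dH_true must be > 0")
        if self.fwhm_true <= 0:
            raise ValueError("fwhm_true must be > 0")
        if self.completion_span <= 0:
            raise ValueError("completion_span must be > 0")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        self.T_grid = np.asarray(self.T_grid, dtype=float)
        if np.any(np.diff(self.T_grid) <= 0):
            raise ValueError("T_grid must be strictly increasing")


def _skewnorm_shape_constants(a: float) -> Tuple[float, float, float]:
    """Mode and half-maximum abscissae of the standard skew-normal."""
    pdf = lambda x: skewnorm.pdf(x, a)
    mode = minimize_scalar(lambda x: -pdf(x), bounds=(-4.0, 4.0),
                           method="bounded").x
    height = pdf(mode)
    left = brentq(lambda x: pdf(x) - height / 2.0, mode - 12.0, mode)
    right = brentq(lambda x: pdf(x) - height / 2.0, mode, mode + 12.0)
    return mode, left, right


def endotherm_peak_shape(T: np.ndarray, Tm: float, fwhm: float,
                         asymmetry: float,
                         completion_span: float = 0.25) -> np.ndarray:
    """Un-normalised tapered skew-normal peak with mode Tm and given FWHM.

    Returns the peak shape (arbitrary scale) together with exact half-maximum
    crossings at ``T_low``/``T_high`` and zero outside
    ``[T_low - span, T_high + span]`` where ``span = completion_span*fwhm``.
    """
    T = np.asarray(T, dtype=float)
    mode, left, right = _skewnorm_shape_constants(asymmetry)
    omega = fwhm / (right - left)
    xi = Tm - omega * mode
    T_low = Tm + (left - mode) * omega
    T_high = Tm + (right - mode) * omega
    span = completion_span * fwhm
    onset, complete = T_low - span, T_high + span

    g = skewnorm.pdf((T - xi) / omega, asymmetry) / omega
    taper = np.ones_like(T)
    taper[T <= onset] = 0.0
    taper[T >= complete] = 0.0
    m = (T > onset) & (T < T_low)
    taper[m] = 0.5 * (1.0 - np.cos(np.pi * (T[m] - onset) / span))
    m = (T > T_high) & (T < complete)
    taper[m] = 0.5 * (1.0 + np.cos(np.pi * (T[m] - T_high) / span))
    return g * taper


def _endotherm_support(Tm, fwhm, asymmetry, completion_span):
    mode, left, right = _skewnorm_shape_constants(asymmetry)
    omega = fwhm / (right - left)
    span = completion_span * fwhm
    return (Tm + (left - mode) * omega - span,
            Tm + (right - mode) * omega + span)


def gen_thermogram(params: EndothermParams) -> Thermogram:
    """Generate a synthetic DSC thermogram with seeded noise.

    Raises ``ValueError`` when ``T_grid`` truncates the transition peak
    (noise-free area error above 0.5 %).
    """
    T = params.T_grid
    peak = endotherm_peak_shape(T, params.Tm_true, params.fwhm_true,
                                params.asymmetry, params.completion_span)
    onset, complete = _endotherm_support(
        params.Tm_true, params.fwhm_true, params.asymmetry,
        params.completion_span)
    T_ref = np.linspace(onset, complete, 4001)
    ref_area = np.trapezoid(
        endotherm_peak_shape(T_ref, params.Tm_true, params.fwhm_true,
                             params.asymmetry, params.completion_span),
        T_ref)
    grid_area = np.trapezoid(peak, T)
    if grid_area <= 0 or abs(grid_area - ref_area) / ref_area > 0.005:
        raise ValueError(
            f"T_grid [{T[0]:.3g}, {T[-1]:.3g}] degC truncates the transition "
            f"peak (support {onset:.3g}-{complete:.3g} degC, area error "
            f"{abs(grid_area - ref_area) / ref_area * 100.0:.2f} %)")
    cp = params.dH_true * peak / grid_area
    cp = cp + params.baseline_intercept + params.baseline_slope * T
    if params.noise_level > 0:
        rng = np.random.default_rng(params.seed)
        cp = cp + rng.normal(0.0, params.noise_level, size=len(T))
    meta = {"seed": params.seed, "heating_rate_C_per_min": 1.0}
    return Thermogram(T, cp, scan_id=0, direction="heating", meta=meta)


# --------------------------------------------------------------------------
# Fluorescence

#: Monomer vibronic band offsets from band I (nm), heights relative to band I,
#: and common Gaussian width (nm). Band I carries the quantitative meaning;
#: bands II-V only shape the spectrum.
_MONOMER_OFFSETS = np.array([0.0, 6.0, 12.0, 19.0, 26.0])
_MONOMER_HEIGHTS = np.array([1.0, 0.80, 0.55, 0.30, 0.12])
_MONOMER_SIGMA = 2.2
_EXCIMER_SIGMA = 32.0


@dataclass
class FluorescenceParams:
    """Ground truth for pyrene monomer/excimer emission.

    ``eta_true`` is the excimer/monomer intensity ratio I(480)/I(376), the
    lateral-pressure parameter. Time traces are sampled for
    ``trace_duration`` seconds at ``sampling_interval`` with relative
    Gaussian noise ``noise_level``; their means are ``monomer_mean`` and
    ``eta_true * monomer_mean`` counts/s.
    """

    eta_true: float = 1.13
    monomer_mean: float = 1.0e5
    monomer_band_nm: float = 376.0
    excimer_band_nm: float = 480.0
    trace_duration: float = 120.0
    sampling_interval: float = 0.5
    noise_level: float = 0.02
    seed: int = 0
    probe_label: str = "Pyr10PC"

    def __post_init__(self):
        if self.eta_true <= 0:
            raise ValueError("eta_true must be > 0")
        if self.monomer_mean <= 0:
            raise ValueError("monomer_mean must be > 0")
        if self.trace_duration <= 0 or self.sampling_interval <= 0:
            raise ValueError("trace duration/interval must be > 0")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")


def emission_spectrum_model(params: FluorescenceParams,
                            wavelength: Optional[np.ndarray] = None
                            ) -> np.ndarray:
    """Noise-free emission spectrum with I(excimer)/I(monomer) = eta_true."""
    if wavelength is None:
        wavelength = np.arange(360.0, 650.0 + 1e-9, 0.5)
    wl = np.asarray(wavelength, dtype=float)
    centers = params.monomer_band_nm + _MONOMER_OFFSETS

    def monomer(w):
        w = np.atleast_1d(np.asarray(w, dtype=float))
        return np.sum(
            _MONOMER_HEIGHTS[None, :]
            * np.exp(-0.5 * ((w[:, None] - centers[None, :])
                             / _MONOMER_SIGMA) ** 2),
            axis=1)

    def excimer_profile(w):
        w = np.asarray(w, dtype=float)
        return np.exp(-0.5 * ((w - params.excimer_band_nm)
                              / _EXCIMER_SIGMA) ** 2)

    m376 = float(monomer(params.monomer_band_nm)[0])
    m480 = float(monomer(params.excimer_band_nm)[0])
    e376 = float(excimer_profile(params.monomer_band_nm))
    # solve (m480 + E)/(m376 + E*e376) = eta for the excimer height E
    E = (params.eta_true * m376 - m480) / (1.0 - params.eta_true * e376)
    if E < 0:
        raise ValueError("eta_true too small for the monomer band overlap")
    return monomer(wl) + E * excimer_profile(wl)


def gen_fluorescence(params: FluorescenceParams
                     ) -> Tuple[EmissionSpectrum, TimeTrace, TimeTrace]:
    """Generate an emission spectrum and monomer/excimer time traces.

    Returns ``(spectrum, monomer_trace, excimer_trace)``; traces are sampled
    at the monomer (376 nm) and excimer (480 nm) wavelengths with seeded
    relative noise. With ``noise_level = 0`` the traces are constant with
    means in the exact ratio ``eta_true``.
    """
    wl = np.arange(360.0, 650.0 + 1e-9, 0.5)
    spec_I = emission_spectrum_model(params, wl) * params.monomer_mean
    rng = np.random.default_rng(params.seed)
    if params.noise_level > 0:
        spec_I = spec_I + rng.normal(
            0.0, params.noise_level * np.clip(spec_I, 0.0, None))

    n = int(round(params.trace_duration / params.sampling_interval))
    t = np.arange(n) * params.sampling_interval
    mon = np.full(n, params.monomer_mean)
    exc = np.full(n, params.eta_true * params.monomer_mean)
    if params.noise_level > 0:
        mon = mon * (1.0 + params.noise_level * rng.normal(size=n))
        exc = exc * (1.0 + params.noise_level * rng.normal(size=n))

    meta = {"probe": params.probe_label, "temperature_C": 37.0,
            "seed": params.seed}
    spectrum = EmissionSpectrum(wl, spec_I, dict(meta))
    monomer_trace = TimeTrace(t, mon, wavelength=params.monomer_band_nm,
                              meta=dict(meta))
    excimer_trace = TimeTrace(t, exc, wavelength=params.excimer_band_nm,
                              meta=dict(meta))
    return spectrum, monomer_trace, excimer_trace
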