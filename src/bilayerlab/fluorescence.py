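"""Lateral-pressure parameter from pyrene excimer fluorescence.

Bis-pyrenyl phosphatidylcholine probes report the packing of the acyl-chain
region through the intramolecular excimer formation rate: the parameter of
lateral pressure is the ratio of the average excimer (480 nm) to monomer
(376 nm) emission intensity,

    eta = <I_excimer> / <I_monomer>,

computed from fixed-wavelength time traces (ratio of trace means, not mean
of per-sample ratios). Its uncertainty comes from first-order (delta
method) propagation of the two standard errors of the mean. Emission
spectra are normalised to the first monomer vibronic band
(I(376 nm) = 100) for presentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .data import EmissionSpectrum, TimeTrace

__all__ = [
    "LateralPressure", "LateralPressureResult",
    "lateral_pressure", "normalize_spectrum",
]

MONOMER_NM = 376.0
EXCIMER_NM = 480.0
_WAVELENGTH_TOL = 5.0


@dataclass
class LateralPressureResult:
    """Excimer/monomer intensity ratio with delta-method uncertainty.

    ``eta_sd`` propagates the standard errors of the two trace means
    (SEM-based, recorded in ``error_basis``).
    """

    eta: float
    eta_sd: float
    mean_monomer: float
    mean_excimer: float
    n_samples_monomer: int
    n_samples_excimer: int
    probe_label: Optional[str] = None
    error_basis: str = "delta-method on SEM of trace means"

    def to_dict(self) -> dict:
        return {
            "eta": self.eta, "eta_sd": self.eta_sd,
            "mean_monomer": self.mean_monomer,
            "mean_excimer": self.mean_excimer,
            "n_samples_monomer": self.n_samples_monomer,
            "n_samples_excimer": self.n_samples_excimer,
            "probe": self.probe_label,
            "error_basis": self.error_basis,
        }

    def summary(self) -> str:
        probe = f" ({self.probe_label})" if self.probe_label else ""
        return (f"lateral pressure parameter{probe}: "
                f"eta = {self.eta:.4f} +/- {self.eta_sd:.4f} "
                f"(excimer/monomer ratio of trace means, "
                f"n = {self.n_samples_excimer}/{self.n_samples_monomer})")


class LateralPressure:
    """Ratio-of-means model for a monomer/excimer trace pair.

    Checks wavelength metadata (376 +/- 5 nm monomer, 480 +/- 5 nm excimer)
    when present, requires at least 10 samples per trace.
    """

    def __init__(self, excimer: TimeTrace, monomer: TimeTrace,
                 probe_label: Optional[str] = None):
        for trace, expect, name in ((monomer, MONOMER_NM, "monomer"),
                                    (excimer, EXCIMER_NM, "excimer")):
            if len(trace) < 10:
                raise ValueError(f"{name} trace has {len(trace)} samples "
                                 "(need >= 10)")
            if (trace.wavelength is not None
                    and abs(trace.wavelength - expect) > _WAVELENGTH_TOL):
                raise ValueError(
                    f"{name} trace recorded at {trace.wavelength} nm, "
                    f"expected {expect} +/- {_WAVELENGTH_TOL} nm "
                    "(traces swapped?)")
        self.excimer = excimer
        self.monomer = monomer
        self.probe_label = probe_label

    def fit(self) -> LateralPressureResult:
        m = self.monomer.I
        e = self.excimer.I
        mean_m = float(np.mean(m))
        mean_e = float(np.mean(e))
        if mean_m <= 0:
            raise ValueError("mean monomer intensity must be positive")
        eta = mean_e / mean_m
        sem_m = float(np.std(m, ddof=1)) / np.sqrt(len(m))
        sem_e = float(np.std(e, ddof=1)) / np.sqrt(len(e))
        eta_sd = abs(eta) * np.sqrt((sem_e / mean_e) ** 2
                                    + (sem_m / mean_m) ** 2) \
            if mean_e != 0 else sem_e / mean_m
        return LateralPressureResult(
            eta=eta, eta_sd=float(eta_sd),
            mean_monomer=mean_m, mean_excimer=mean_e,
            n_samples_monomer=len(m), n_samples_excimer=len(e),
            probe_label=self.probe_label)


def lateral_pressure(excimer: TimeTrace, monomer: TimeTrace,
                     probe_label: Optional[str] = None
                     ) -> LateralPressureResult:
    """eta = mean(excimer)/mean(monomer) with propagated uncertainty."""
    return LateralPressure(excimer, monomer, probe_label).fit()


def normalize_spectrum(spec: EmissionSpectrum,
                       band_nm: float = MONOMER_NM,
                       search_halfwidth: float = 3.0) -> EmissionSpectrum:
    """Scale a spectrum so the monomer band-I maximum equals 100.

    The band maximum is located as the largest intensity within
    ``band_nm +/- search_halfwidth`` (tolerant to small calibration
    offsets). Scale-invariant: any uniform rescaling of the input yields
    the identical normalised output.
    """
    wl = spec.wavelength
    m = (wl >= band_nm - search_halfwidth) & (wl <= band_nm + search_halfwidth)
    if not np.any(m):
        raise ValueError(
            f"spectrum does not cover the monomer band at {band_nm} nm")
    peak = float(np.max(spec.I[m]))
    if peak <= 0:
        raise ValueError("zero intensity at the monomer band; cannot "
                         "normalise")
    meta = dict(spec.meta)
    meta["normalisation"] = f"I({band_nm:g} nm) = 100"
    return EmissionSpectrum(wl.copy(), spec.I * (100.0 / peak), meta)
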