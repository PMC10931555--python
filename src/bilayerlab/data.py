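"""In-memory containers for the measured quantities.

All modules exchange data through four small record types:

``ScatteringCurve``
    a 1D scattering pattern I(q), shared by SANS, SAXS and WAXS analyses,
    with q in nm^-1 and intensity in relative units;
``Thermogram``
    a DSC trace of excess specific heat versus temperature;
``EmissionSpectrum`` / ``TimeTrace``
    a fluorescence emission spectrum I(lambda) and a fixed-wavelength
    intensity time series.

The containers validate their invariants on construction and are otherwise
plain dataclasses wrapping numpy arrays plus a free-form ``meta`` dict used
for provenance (modality, temperature, sample label, subtracted constants).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "ScatteringCurve",
    "Thermogram",
    "EmissionSpectrum",
    "TimeTrace",
    "angstrom_inv_to_nm_inv",
]


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass
class ScatteringCurve:
    """A 1D scattering curve (q, I, optional per-point sigma).

    Parameters
    ----------
    q : array_like
        Momentum transfer in nm^-1, strictly increasing and positive.
    I : array_like
        Scattered intensity in relative units.
    sigma : array_like, optional
        Per-point uncertainty of ``I``.
    meta : dict
        Provenance: ``modality`` ("SANS"/"SAXS"/"WAXS"), ``temperature_C``,
        ``sample``, and any record left by processing steps (for example the
        subtracted incoherent background).
    """

    q: np.ndarray
    I: np.ndarray
    sigma: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = _as_float_array(self.q, "q")
        self.I = _as_float_array(self.I, "I")
        if len(self.q) != len(self.I):
            raise ValueError("q and I must have the same length")
        if len(self.q) == 0:
            raise ValueError("empty curve")
        if np.any(self.q <= 0):
            raise ValueError("q must be strictly positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if not np.all(np.isfinite(self.I)):
            raise ValueError("I must be finite")
        if self.sigma is not None:
            self.sigma = _as_float_array(self.sigma, "sigma")
            if len(self.sigma) != len(self.q):
                raise ValueError("sigma must match q in length")

    def __len__(self) -> int:
        return len(self.q)

    def window(self, q_min: float, q_max: float) -> "ScatteringCurve":
        """Return the sub-curve with q_min <= q <= q_max."""
        if q_min > q_max:
            raise ValueError("q_min must not exceed q_max")
        m = (self.q >= q_min) & (self.q <= q_max)
        if not np.any(m):
            raise ValueError(
                f"window [{q_min}, {q_max}] nm^-1 contains no data "
                f"(curve spans {self.q[0]:.4g}-{self.q[-1]:.4g} nm^-1)"
            )
        sig = self.sigma[m] if self.sigma is not None else None
        return ScatteringCurve(self.q[m], self.I[m], sig, dict(self.meta))

    def with_intensity(self, I, sigma=None, **meta_updates) -> "ScatteringCurve":
        new_meta = dict(self.meta)
        new_meta.update(meta_updates)
        return ScatteringCurve(
            self.q.copy(), I,
            sigma if sigma is not None else (
                self.sigma.copy() if self.sigma is not None else None),
            new_meta,
        )


@dataclass
class Thermogram:
    """Excess specific heat versus temperature from a DSC scan.

    ``cp_excess`` is in J g^-1 degC^-1 (normalised to sample mass),
    ``T`` in degC, strictly monotone.
    """

    T: np.ndarray
    cp_excess: np.ndarray
    scan_id: int = 0
    direction: str = "heating"
    sample_mass_normalized: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.T = _as_float_array(self.T, "T")
        self.cp_excess = _as_float_array(self.cp_excess, "cp_excess")
        if len(self.T) != len(self.cp_excess):
            raise ValueError("T and cp_excess must have the same length")
        if len(self.T) < 2:
            raise ValueError("thermogram needs at least two points")
        dT = np.diff(self.T)
        if not (np.all(dT > 0) or np.all(dT < 0)):
            raise ValueError("T must be strictly monotone")
        if self.direction not in ("heating", "cooling"):
            raise ValueError("direction must be 'heating' or 'cooling'")

    def ascending(self) -> "Thermogram":
        """Return a copy with T in increasing order."""
        if self.T[1] > self.T[0]:
            return self
        return replace(self, T=self.T[::-1].copy(),
                       cp_excess=self.cp_excess[::-1].copy())


@dataclass
class EmissionSpectrum:
    """Fluorescence emission spectrum I(lambda), wavelength in nm."""

    wavelength: np.ndarray
    I: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelength = _as_float_array(self.wavelength, "wavelength")
        self.I = _as_float_array(self.I, "I")
        if len(self.wavelength) != len(self.I):
            raise ValueError("wavelength and I must have the same length")
        if np.any(np.diff(self.wavelength) <= 0):
            raise ValueError("wavelength must be strictly increasing")


@dataclass
class TimeTrace:
    """Fixed-wavelength fluorescence intensity versus time."""

    t: np.ndarray
    I: np.ndarray
    wavelength: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = _as_float_array(self.t, "t")
        self.I = _as_float_array(self.I, "I")
        if len(self.t) != len(self.I):
            raise ValueError("t and I must have the same length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)


def angstrom_inv_to_nm_inv(q_angstrom: np.ndarray) -> np.ndarray:
    """Convert momentum transfer from A^-1 to nm^-1 (multiply by 10)."""
    return np.asarray(q_angstrom, dtype=float) * 10.0
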