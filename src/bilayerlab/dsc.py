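"""Gel-to-fluid transition parameters from DSC thermograms.

The main phase transition of a lipid mixture appears as a broad endotherm
in excess specific heat. The analysis follows standard calorimetric
practice: subtract a linear baseline anchored in flat windows flanking the
transition, take the transition temperature Tm from the maximum of a
locally smoothed curve, the calorimetric enthalpy dH from the trapezoidal
integral, and the transition width as the full width at half maximum.
Replicate heating scans are combined by ``average_scans``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.signal import savgol_filter

from .data import Thermogram

__all__ = [
    "baseline_correct", "transition_params", "average_scans",
    "TransitionModel", "ThermogramResult", "AveragedThermogramResult",
]


def _window_stats(T, cp, window, name):
    lo, hi = window
    tol = 1e-8 * (T[-1] - T[0])
    if lo < T[0] - tol or hi > T[-1] + tol:
        raise ValueError(f"{name} window [{lo}, {hi}] degC outside the "
                         f"scanned range [{T[0]:.3g}, {T[-1]:.3g}]")
    m = (T >= lo) & (T <= hi)
    if m.sum() < 5:
        raise ValueError(f"{name} window holds {int(m.sum())} points "
                         "(need >= 5)")
    return m


def baseline_correct(tg: Thermogram,
                     pre_window: Tuple[float, float],
                     post_window: Tuple[float, float]) -> Thermogram:
    """Subtract the straight line through the two flanking-window means.

    The line passes through (mean T, mean cp) of each window; after
    correction the curve is ~0 within both windows. Raises when a window
    visibly overlaps the transition (half-window mean residuals beyond
    3 sigma of the point noise and 5 % of the peak height).
    """
    tg = tg.ascending()
    T, cp = tg.T, tg.cp_excess
    m_pre = _window_stats(T, cp, pre_window, "pre")
    m_post = _window_stats(T, cp, post_window, "post")
    t1, c1 = float(T[m_pre].mean()), float(cp[m_pre].mean())
    t2, c2 = float(T[m_post].mean()), float(cp[m_post].mean())
    if t2 == t1:
        raise ValueError("baseline windows coincide")
    slope = (c2 - c1) / (t2 - t1)
    intercept = c1 - slope * t1
    corrected = cp - (intercept + slope * T)

    peak_height = float(np.max(np.abs(corrected)))
    for m, name in ((m_pre, "pre"), (m_post, "post")):
        vals = corrected[m]
        noise_sd = 1.4826 * np.median(np.abs(np.diff(vals))) / np.sqrt(2.0)
        half = len(vals) // 2
        for part in (vals[:half], vals[half:]):
            mean_resid = abs(float(np.mean(part)))
            if (mean_resid > 3.0 * max(noise_sd, 1e-12)
                    and mean_resid > 0.05 * peak_height):
                raise ValueError(
                    f"{name} baseline window overlaps the transition "
                    f"(mean residual {mean_resid:.4g} J/g/degC)")

    meta = dict(tg.meta)
    meta.update(baseline_intercept=intercept, baseline_slope=slope,
                baseline_pre_window=list(pre_window),
                baseline_post_window=list(post_window),
                baseline_model="linear (two-point, window means)")
    return Thermogram(T, corrected, scan_id=tg.scan_id,
                      direction=tg.direction,
                      sample_mass_normalized=tg.sample_mass_normalized,
                      meta=meta)


@dataclass
class ThermogramResult:
    """Transition parameters of a single baseline-corrected scan."""

    Tm: float
    dH: float
    fwhm: float
    peak_height: float
    baseline: Tuple[float, float]  # (intercept, slope) subtracted earlier
    pre_window: Optional[Tuple[float, float]]
    post_window: Optional[Tuple[float, float]]
    direction: str = "heating"
    scan_id: int = 0
    T: np.ndarray = field(default=None, repr=False)
    cp: np.ndarray = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "Tm_C": self.Tm, "dH_J_per_g": self.dH, "fwhm_C": self.fwhm,
            "peak_height_J_per_g_C": self.peak_height,
            "baseline_intercept": self.baseline[0],
            "baseline_slope": self.baseline[1],
            "pre_window_C": list(self.pre_window) if self.pre_window else None,
            "post_window_C": (list(self.post_window)
                              if self.post_window else None),
            "direction": self.direction, "scan_id": self.scan_id,
            "baseline_model_assumed": "linear (two-point, window means)",
        }

    def summary(self) -> str:
        return "\n".join([
            "DSC transition parameters",
            "-------------------------",
            f"Tm   : {self.Tm:.2f} degC (maximum of smoothed peak)",
            f"dH   : {self.dH:.2f} J/g (trapezoidal area)",
            f"FWHM : {self.fwhm:.2f} degC",
            f"baseline: intercept {self.baseline[0]:.4g}, "
            f"slope {self.baseline[1]:.4g} J/g/degC per degC",
        ])

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.T, self.cp, lw=1)
        ax.axvline(self.Tm, ls="--", color="k", lw=0.8,
                   label=f"Tm = {self.Tm:.2f} degC")
        ax.set_xlabel("T (degC)")
        ax.set_ylabel(r"excess $c_p$ (J g$^{-1}$ degC$^{-1}$)")
        ax.legend()
        return ax


def transition_params(tg: Thermogram,
                      smooth_window: int = 11) -> ThermogramResult:
    """Tm, dH and FWHM of a baseline-corrected endotherm.

    Tm is the temperature of the maximum of a local-quadratic
    (Savitzky-Golay) smoothed curve with sub-grid parabolic refinement;
    dH the trapezoidal integral of the raw corrected curve; FWHM the
    half-height width of the smoothed curve with crossings located by
    linear interpolation (leftmost crossing pair).
    """
    tg = tg.ascending()
    T, cp = tg.T, tg.cp_excess
    window = min(smooth_window, len(cp))
    if window % 2 == 0:
        window -= 1
    smooth = savgol_filter(cp, window, 2) if window >= 5 else cp.copy()

    i_max = int(np.argmax(smooth))
    height = float(smooth[i_max])
    # smoothing overshoot can turn a purely negative (exothermic/inverted)
    # curve weakly positive; demand that the maximum dominates the dip
    if height <= 0 or height < 0.01 * abs(float(np.min(smooth))):
        raise ValueError("no positive peak (cooling scan or "
                         "over-corrected baseline?)")
    # parabolic sub-grid refinement of the maximum
    Tm = float(T[i_max])
    if 0 < i_max < len(T) - 1:
        y0, y1, y2 = smooth[i_max - 1], smooth[i_max], smooth[i_max + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:
            delta = 0.5 * (y0 - y2) / denom
            if abs(delta) <= 1.0:
                Tm = float(T[i_max] + delta * (T[i_max] - T[i_max - 1]))

    dH = float(np.trapezoid(cp, T))
    half = height / 2.0

    below_left = np.where(smooth[:i_max] < half)[0]
    below_right = np.where(smooth[i_max:] < half)[0]
    if len(below_left) == 0 or len(below_right) == 0:
        raise ValueError("half-maximum level not crossed on both sides; "
                         "peak truncated by the scan range")
    il = below_left[-1]
    T_left = float(np.interp(half, [smooth[il], smooth[il + 1]],
                             [T[il], T[il + 1]]))
    ir = i_max + below_right[0]
    T_right = float(np.interp(half, [smooth[ir], smooth[ir - 1]],
                              [T[ir], T[ir - 1]]))

    meta = tg.meta
    return ThermogramResult(
        Tm=Tm, dH=dH, fwhm=T_right - T_left, peak_height=height,
        baseline=(meta.get("baseline_intercept", 0.0),
                  meta.get("baseline_slope", 0.0)),
        pre_window=tuple(meta["baseline_pre_window"])
        if "baseline_pre_window" in meta else None,
        post_window=tuple(meta["baseline_post_window"])
        if "baseline_post_window" in meta else None,
        direction=tg.direction, scan_id=tg.scan_id,
        T=T, cp=cp)


class TransitionModel:
    """DSC transition model: optional baseline correction + peak analysis.

    With ``pre_window``/``post_window`` given, ``fit()`` baseline-corrects
    first; otherwise the input is taken as already corrected.
    """

    def __init__(self, tg: Thermogram,
                 pre_window: Optional[Tuple[float, float]] = None,
                 post_window: Optional[Tuple[float, float]] = None,
                 smooth_window: int = 11):
        if (pre_window is None) != (post_window is None):
            raise ValueError("give both baseline windows or neither")
        self.tg = tg
        self.pre_window = pre_window
        self.post_window = post_window
        self.smooth_window = smooth_window

    def fit(self) -> ThermogramResult:
        tg = self.tg
        if self.pre_window is not None:
            tg = baseline_correct(tg, self.pre_window, self.post_window)
        return transition_params(tg, smooth_window=self.smooth_window)


@dataclass
class AveragedThermogramResult:
    """Mean and SD of transition parameters over replicate heating scans."""

    Tm: float
    Tm_sd: float
    dH: float
    dH_sd: float
    fwhm: float
    fwhm_sd: float
    n_scans: int

    def to_dict(self) -> dict:
        return {"Tm_C": self.Tm, "Tm_sd_C": self.Tm_sd,
                "dH_J_per_g": self.dH, "dH_sd_J_per_g": self.dH_sd,
                "fwhm_C": self.fwhm, "fwhm_sd_C": self.fwhm_sd,
                "n_scans": self.n_scans}

    def summary(self) -> str:
        return (f"mean of {self.n_scans} scans: "
                f"Tm = {self.Tm:.2f} +/- {self.Tm_sd:.2f} degC, "
                f"dH = {self.dH:.2f} +/- {self.dH_sd:.2f} J/g, "
                f"FWHM = {self.fwhm:.2f} +/- {self.fwhm_sd:.2f} degC")


def average_scans(results: List[ThermogramResult]) -> AveragedThermogramResult:
    """Per-parameter mean and SD over replicate scans of one sample."""
    if len(results) < 2:
        raise ValueError("need at least 2 scans to average")
    directions = {r.direction for r in results}
    if len(directions) > 1:
        raise ValueError(f"mixed scan directions {sorted(directions)}; "
                         "average heating and cooling scans separately")
    tm = np.array([r.Tm for r in results])
    dh = np.array([r.dH for r in results])
    fw = np.array([r.fwhm for r in results])
    return AveragedThermogramResult(
        Tm=float(tm.mean()), Tm_sd=float(tm.std(ddof=1)),
        dH=float(dh.mean()), dH_sd=float(dh.std(ddof=1)),
        fwhm=float(fw.mean()), fwhm_sd=float(fw.std(ddof=1)),
        n_scans=len(results))
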