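"""Lamellar repeat distance from SAXS and crystalline-drug detection in WAXS.

The lamellar stacking period of multilamellar vesicles follows from the
first diffraction order via d = 2 pi / q1; each order is fitted with a
Lorentzian plus a local linear background (``LamellarModel``). The broad
WAXS band near 14 nm^-1 reports liquid-like acyl-chain packing;
``WaxsModel`` fits it and flags sharp superposed peaks (undissolved
crystalline drug) found as positive residual excursions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from lmfit.models import LinearModel, LorentzianModel
from scipy.signal import find_peaks, peak_widths, savgol_filter

from .data import ScatteringCurve

__all__ = [
    "LamellarModel", "LamellarResult", "fit_lamellar_peaks",
    "WaxsModel", "WaxsResult", "analyze_waxs",
    "water_layer", "PeakNotFoundError",
]

TWO_PI = 2.0 * np.pi


class PeakNotFoundError(ValueError):
    """No diffraction peak detectable above the background."""


@dataclass
class FittedPeak:
    center: float
    hwhm: float
    height: float
    center_sd: float


@dataclass
class LamellarResult:
    """Fitted lamellar diffraction orders and the repeat distance.

    ``d = 2 pi / q1`` exactly, with ``d_sd`` propagated from the
    first-order center uncertainty; ``order_ratio`` is q2/q1 (2 for an
    ideal lamellar stack).
    """

    peaks: List[FittedPeak]
    bg_intercept: float
    bg_slope: float
    d: float
    d_sd: float
    order_ratio: Optional[float]
    fit_windows: List[Tuple[float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "peaks": [{"center_nm^-1": p.center, "hwhm_nm^-1": p.hwhm,
                       "height": p.height, "center_sd_nm^-1": p.center_sd}
                      for p in self.peaks],
            "bg_intercept": self.bg_intercept,
            "bg_slope": self.bg_slope,
            "d_nm": self.d, "d_sd_nm": self.d_sd,
            "order_ratio": self.order_ratio,
        }

    def summary(self) -> str:
        lines = ["Lamellar phase fit", "------------------"]
        for i, p in enumerate(self.peaks, start=1):
            lines.append(
                f"order {i}: q = {p.center:.4f} +/- {p.center_sd:.4f} nm^-1, "
                f"HWHM = {p.hwhm:.4f} nm^-1")
        lines.append(f"repeat distance d = 2pi/q1 = {self.d:.4f} "
                     f"+/- {self.d_sd:.4f} nm")
        if self.order_ratio is not None:
            lines.append(f"order ratio q2/q1 = {self.order_ratio:.4f} "
                         f"(2 expected for a lamellar stack)")
        return "\n".join(lines)


def _detect_first_order(q, I, min_prominence_frac=0.02):
    """Smoothed-curve peak picking; returns candidate peak indices."""
    if len(I) > 15:
        window = min(11, len(I) - (1 - len(I) % 2))
        smooth = savgol_filter(I, window, 2)
    else:
        smooth = I
    span = float(np.max(smooth) - np.median(smooth))
    noise = 1.4826 * np.median(np.abs(np.diff(I))) / np.sqrt(2.0)
    # absolute floor keeps float-level wiggles of featureless curves out
    prominence = max(3.0 * noise, min_prominence_frac * span,
                     1e-9 * float(np.max(np.abs(I))) + 1e-300)
    idx, props = find_peaks(smooth, prominence=prominence)
    return idx, smooth


class LamellarModel:
    """Per-order Lorentzian + linear-background fit of a lamellar pattern.

    Each diffraction order is fitted in a local window (default +/- 5
    half-width guesses around the expected center) — robust against diffuse
    scattering between orders. Initial centers come from a smoothed-curve
    peak picker, or from ``init_d`` when given.
    """

    def __init__(self, curve: ScatteringCurve, n_orders: int = 2,
                 init_d: Optional[float] = None,
                 q_max: Optional[float] = None,
                 window_halfwidths: float = 5.0):
        if n_orders < 1:
            raise ValueError("n_orders must be >= 1")
        self.curve = curve
        self.n_orders = int(n_orders)
        self.init_d = init_d
        self.q_max = q_max
        self.window_halfwidths = float(window_halfwidths)

    def _first_order_guess(self, q, I):
        if self.init_d is not None:
            return TWO_PI / self.init_d, None
        idx, smooth = _detect_first_order(q, I)
        if len(idx) == 0:
            raise PeakNotFoundError(
                "no diffraction peak detected above the background")
        # lowest-q detected peak is the first structural order
        first = int(idx[0])
        widths = peak_widths(smooth, [first], rel_height=0.5)[0]
        dq = float(np.median(np.diff(q)))
        hwhm_guess = max(widths[0] * dq / 2.0, 2.0 * dq)
        return float(q[first]), hwhm_guess

    def _fit_one(self, q, I, sigma, center0, hwhm0):
        lo = center0 - self.window_halfwidths * hwhm0
        hi = center0 + self.window_halfwidths * hwhm0
        m = (q >= lo) & (q <= hi)
        if m.sum() < 7:
            raise PeakNotFoundError(
                f"fewer than 7 points around expected peak at "
                f"{center0:.3f} nm^-1")
        qw, Iw = q[m], I[m]
        peak = LorentzianModel(prefix="pk_")
        bg = LinearModel(prefix="bg_")
        model = peak + bg
        bg_slope0 = (Iw[-1] - Iw[0]) / (qw[-1] - qw[0])
        bg_int0 = Iw[0] - bg_slope0 * qw[0]
        height0 = max(float(np.max(Iw) - np.median(Iw)), 1e-12)
        params = model.make_params(
            pk_center=dict(value=center0, min=lo, max=hi),
            pk_sigma=dict(value=hwhm0, min=1e-5, max=(hi - lo)),
            pk_amplitude=dict(value=height0 * np.pi * hwhm0, min=0.0),
            bg_slope=bg_slope0, bg_intercept=bg_int0,
        )
        weights = None
        if sigma is not None:
            sw = sigma[m]
            if np.all(sw > 0):
                weights = 1.0 / sw
        out = model.fit(Iw, params, x=qw, weights=weights)
        if not out.success:
            raise RuntimeError(
                f"Lorentzian fit failed near {center0:.3f} nm^-1: "
                f"{out.message}")
        center = float(out.params["pk_center"].value)
        center_sd = float(out.params["pk_center"].stderr or 0.0)
        hwhm = float(out.params["pk_sigma"].value)
        height = float(out.params["pk_amplitude"].value / (np.pi * hwhm))
        return (FittedPeak(center, hwhm, height, center_sd),
                float(out.params["bg_intercept"].value),
                float(out.params["bg_slope"].value), (lo, hi))

    def fit(self) -> LamellarResult:
        curve = self.curve
        q_max = self.q_max
        if q_max is None:
            # keep clear of the WAXS chain band
            q_max = min(curve.q[-1], 8.0)
        sub = curve.window(curve.q[0], q_max)
        q, I = sub.q, sub.I
        sigma = sub.sigma

        q1_guess, hwhm_guess = self._first_order_guess(q, I)
        if hwhm_guess is None:
            hwhm_guess = 0.05
        peaks: List[FittedPeak] = []
        windows = []
        bg_i = bg_s = 0.0
        for n in range(1, self.n_orders + 1):
            center0 = (n * peaks[0].center) if peaks else q1_guess
            peak, bg_i, bg_s, win = self._fit_one(
                q, I, sigma, center0, hwhm_guess)
            peaks.append(peak)
            windows.append(win)
        q1 = peaks[0].center
        d = TWO_PI / q1
        d_sd = TWO_PI * peaks[0].center_sd / q1 ** 2
        ratio = peaks[1].center / q1 if len(peaks) >= 2 else None
        return LamellarResult(
            peaks=peaks, bg_intercept=bg_i, bg_slope=bg_s,
            d=d, d_sd=d_sd, order_ratio=ratio, fit_windows=windows)


def fit_lamellar_peaks(curve: ScatteringCurve, n_orders: int = 2,
                       init_d: Optional[float] = None,
                       **kwargs) -> LamellarResult:
    """Fit ``n_orders`` lamellar diffraction orders; see LamellarModel."""
    return LamellarModel(curve, n_orders=n_orders, init_d=init_d,
                         **kwargs).fit()


def water_layer(d: float, d_L: float) -> float:
    """Water-layer thickness d_W = d - d_L of a lamellar stack (nm)."""
    if d_L <= 0:
        raise ValueError("bilayer thickness d_L must be > 0")
    if d <= d_L:
        raise ValueError(
            f"repeat distance d = {d} nm must exceed bilayer thickness "
            f"d_L = {d_L} nm")
    return d - d_L


@dataclass
class SharpPeak:
    center: float
    hwhm: float
    height: float
    shares_run: bool  # True when several maxima sit in one residual excursion


@dataclass
class WaxsResult:
    """Broad chain-band fit plus sharp crystalline-peak detection."""

    broad_center: float
    broad_hwhm: float
    broad_height: float
    bg_intercept: float
    bg_slope: float
    sharp_peaks: List[SharpPeak]
    classification: str  # "fluid-only" | "fluid+crystalline"
    partially_resolved: bool

    def to_dict(self) -> dict:
        return {
            "broad_center_nm^-1": self.broad_center,
            "broad_hwhm_nm^-1": self.broad_hwhm,
            "broad_height": self.broad_height,
            "bg_intercept": self.bg_intercept,
            "bg_slope": self.bg_slope,
            "sharp_peaks": [{"center_nm^-1": p.center, "hwhm_nm^-1": p.hwhm,
                             "height": p.height,
                             "shares_run": p.shares_run}
                            for p in self.sharp_peaks],
            "classification": self.classification,
            "partially_resolved": self.partially_resolved,
        }

    def summary(self) -> str:
        lines = [
            "WAXS chain-band analysis",
            "------------------------",
            f"broad band: center {self.broad_center:.3f} nm^-1, "
            f"HWHM {self.broad_hwhm:.3f} nm^-1",
            f"classification: {self.classification}",
        ]
        for p in self.sharp_peaks:
            note = "  [shares residual run]" if p.shares_run else ""
            lines.append(f"sharp peak at q = {p.center:.3f} nm^-1 "
                         f"(HWHM ~ {p.hwhm:.3f}){note}")
        if self.partially_resolved:
            lines.append("note: neighbouring sharp peaks only partially "
                         "resolved (shared residual excursion)")
        return "\n".join(lines)


class WaxsModel:
    """Broad-band + linear-background fit with sharp-peak detection.

    The broad liquid-chain band is fitted as a Lorentzian over a linear
    background with one robust re-fit pass (points beyond 3 robust SD
    masked) so sharp crystalline peaks do not bias it; sharp peaks are then
    detected as positive residual excursions above ``z_threshold`` robust
    standard deviations and classified as crystalline when their width is
    below ``sharp_width_frac`` of the broad width.
    """

    def __init__(self, curve: ScatteringCurve,
                 window: Tuple[float, float] = (10.0, 18.0),
                 z_threshold: float = 4.0,
                 sharp_width_frac: float = 0.2):
        self.curve = curve
        self.window = window
        self.z_threshold = float(z_threshold)
        self.sharp_width_frac = float(sharp_width_frac)

    def _fit_broad(self, q, I, keep):
        model = LorentzianModel(prefix="br_") + LinearModel(prefix="bg_")
        center0 = float(q[keep][np.argmax(I[keep])])
        params = model.make_params(
            br_center=dict(value=center0, min=q[0], max=q[-1]),
            br_sigma=dict(value=1.5, min=0.2, max=(q[-1] - q[0])),
            br_amplitude=dict(value=float(np.ptp(I[keep])) * np.pi * 1.5,
                              min=0.0),
            bg_slope=0.0, bg_intercept=float(np.min(I[keep])),
        )
        out = model.fit(I[keep], params, x=q[keep])
        return out

    def fit(self) -> WaxsResult:
        try:
            sub = self.curve.window(*self.window)
        except ValueError as err:
            raise ValueError(f"empty WAXS window: {err}") from err
        q, I = sub.q, sub.I
        keep = np.ones(len(q), dtype=bool)
        out = self._fit_broad(q, I, keep)
        resid = I - out.eval(x=q)
        mad = np.median(np.abs(resid - np.median(resid)))
        robust_sd = 1.4826 * mad
        if robust_sd > 0:
            keep = np.abs(resid - np.median(resid)) < 3.0 * robust_sd
            if keep.sum() > 10:
                out = self._fit_broad(q, I, keep)
                resid = I - out.eval(x=q)
                mad = np.median(np.abs(resid[keep] - np.median(resid[keep])))
                robust_sd = 1.4826 * mad

        broad_center = float(out.params["br_center"].value)
        broad_hwhm = float(out.params["br_sigma"].value)
        broad_height = float(
            out.params["br_amplitude"].value / (np.pi * broad_hwhm))
        threshold = max(self.z_threshold * robust_sd,
                        1e-6 * float(np.max(I)))

        peak_idx, _ = find_peaks(resid, height=threshold)
        dq = float(np.median(np.diff(q)))
        above = resid > threshold
        run_id = np.cumsum(np.diff(np.concatenate(
            [[False], above])).astype(int).clip(min=0))
        sharp: List[SharpPeak] = []
        run_of_peak = {}
        for i in peak_idx:
            run_of_peak[i] = int(run_id[i]) if above[i] else -1
        run_counts = {}
        for r in run_of_peak.values():
            run_counts[r] = run_counts.get(r, 0) + 1
        if len(peak_idx) > 0:
            fwhms = peak_widths(resid, peak_idx, rel_height=0.5)[0] * dq
            for i, fwhm in zip(peak_idx, fwhms):
                hwhm = fwhm / 2.0
                if hwhm >= self.sharp_width_frac * broad_hwhm:
                    continue  # too broad to be a crystalline reflection
                sharp.append(SharpPeak(
                    center=float(q[i]), hwhm=float(hwhm),
                    height=float(resid[i]),
                    shares_run=run_counts.get(run_of_peak[i], 0) > 1))
        partially = any(p.shares_run for p in sharp)
        classification = "fluid+crystalline" if sharp else "fluid-only"
        return WaxsResult(
            broad_center=broad_center, broad_hwhm=broad_hwhm,
            broad_height=broad_height,
            bg_intercept=float(out.params["bg_intercept"].value),
            bg_slope=float(out.params["bg_slope"].value),
            sharp_peaks=sharp, classification=classification,
            partially_resolved=partially)


def analyze_waxs(curve: ScatteringCurve, **kwargs) -> WaxsResult:
    """Fit the broad WAXS band and detect sharp crystalline peaks."""
    return WaxsModel(curve, **kwargs).fit()
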