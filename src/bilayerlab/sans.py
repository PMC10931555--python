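"""Bilayer thickness from SANS curves by Kratky-Porod analysis.

For dilute unilamellar vesicles whose radius is large compared with 1/q the
coherent intensity follows the thin-sheet Guinier form

    I(q) = C exp(-q^2 Rg^2) / q^2,

so ln(I q^2) is linear in q^2 with slope -Rg^2, where Rg is the
one-dimensional radius of gyration of the bilayer thickness profile; the
sheet thickness follows from d_g^2 = 12 Rg^2. The workflow is

1. ``subtract_incoherent_background`` — remove the flat (mainly hydrogen
   incoherent) level estimated as the mean intensity over a high-q tail
   window where the coherent signal has died out;
2. ``KratkyPorod(curve).fit()`` — ordinary least squares of ln(I q^2) on
   q^2 over the fit window (default 0.31-1.14 nm^-1, the thin-sheet
   regime), with d_g and its uncertainty propagated from the slope;
3. ``guinier_validity`` — report max(q) * Rg over the window; the Guinier
   form is only controlled for q Rg < 1, so results beyond that carry a
   warning flag.

The regression is unweighted by default (sigma-weighted available), the
goodness gate r^2 >= 0.993 flags rather than fails a result, and the
reported d_g uncertainty propagates the slope standard deviation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .data import ScatteringCurve
from .synthetic import SQRT12

__all__ = [
    "subtract_incoherent_background",
    "KratkyPorod", "KratkyPorodResult",
    "kratky_porod_fit", "guinier_validity", "GuinierDiagnostic",
]


def subtract_incoherent_background(
        curve: ScatteringCurve,
        tail_window: Tuple[float, float] = (4.0, 5.0)) -> ScatteringCurve:
    """Subtract the flat incoherent background estimated from a high-q tail.

    The mean intensity over ``tail_window`` is subtracted from every point
    and recorded in ``meta['incoherent_background']``. The window must lie
    within the measured q-range and contain at least 5 points.
    """
    q_lo, q_hi = tail_window
    if q_lo < curve.q[0] or q_hi > curve.q[-1]:
        raise ValueError(
            f"tail window [{q_lo}, {q_hi}] outside data range "
            f"[{curve.q[0]:.4g}, {curve.q[-1]:.4g}] nm^-1")
    mask = (curve.q >= q_lo) & (curve.q <= q_hi)
    if mask.sum() < 5:
        raise ValueError(
            f"tail window contains only {int(mask.sum())} points (need >= 5)")
    background = float(np.mean(curve.I[mask]))
    return curve.with_intensity(
        curve.I - background,
        incoherent_background=background,
        background_tail_window=[q_lo, q_hi],
    )


@dataclass
class KratkyPorodResult:
    """Kratky-Porod regression result.

    ``slope``/``intercept`` are the coefficients of ln(I q^2) on q^2;
    ``Rg = sqrt(-slope)`` and ``d_g = sqrt(12) Rg`` in nm, with standard
    deviations propagated from the slope alone. ``conforming`` is False
    when r^2 falls below the configured threshold.
    """

    slope: float
    intercept: float
    slope_sd: float
    intercept_sd: float
    r2: float
    Rg: float
    Rg_sd: float
    d_g: float
    d_g_sd: float
    q_window: Tuple[float, float]
    n_points: int
    q_max_used: float
    conforming: bool
    r2_threshold: float
    weighted: bool
    q2: np.ndarray = field(repr=False)
    log_iq2: np.ndarray = field(repr=False)

    @property
    def fit_line(self) -> np.ndarray:
        return self.intercept + self.slope * self.q2

    def plot_table(self):
        """(q^2, ln(I q^2), fit line) as a DataFrame, for plotting/export."""
        import pandas as pd

        return pd.DataFrame({
            "q2_nm^-2": self.q2,
            "ln_Iq2": self.log_iq2,
            "fit": self.fit_line,
        })

    def plot(self, ax=None):
        """Kratky-Porod plot of the fitted window."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.q2, self.log_iq2, "o", ms=4, label="data")
        ax.plot(self.q2, self.fit_line, "-",
                label=f"fit: Rg = {self.Rg:.3f} nm")
        ax.set_xlabel(r"$q^2$ (nm$^{-2}$)")
        ax.set_ylabel(r"$\ln(I q^2)$")
        ax.legend()
        return ax

    def to_dict(self) -> dict:
        return {
            "slope": self.slope, "intercept": self.intercept,
            "slope_sd": self.slope_sd, "r2": self.r2,
            "Rg_nm": self.Rg, "Rg_sd_nm": self.Rg_sd,
            "d_g_nm": self.d_g, "d_g_sd_nm": self.d_g_sd,
            "q_window_nm^-1": list(self.q_window),
            "n_points": self.n_points,
            "q_max_used_nm^-1": self.q_max_used,
            "conforming": self.conforming,
            "r2_threshold": self.r2_threshold,
            "weighted": self.weighted,
        }

    def summary(self) -> str:
        flag = "" if self.conforming else (
            f"  [flag: r2 < {self.r2_threshold}]")
        lines = [
            "Kratky-Porod thin-sheet fit",
            "---------------------------",
            f"q window        : {self.q_window[0]:.3f}-{self.q_window[1]:.3f}"
            f" nm^-1  ({self.n_points} points)",
            f"slope           : {self.slope:.5f} +/- {self.slope_sd:.5f} nm^2",
            f"r^2             : {self.r2:.5f}{flag}",
            f"Rg              : {self.Rg:.4f} +/- {self.Rg_sd:.4f} nm",
            f"d_g = sqrt(12)Rg: {self.d_g:.4f} +/- {self.d_g_sd:.4f} nm",
            f"max(q)*Rg       : {self.q_max_used * self.Rg:.3f}"
            + ("  [beyond Guinier regime]"
               if self.q_max_used * self.Rg > 1.0 else ""),
        ]
        return "\n".join(lines)


class KratkyPorod:
    """Thin-sheet Kratky-Porod model for a background-subtracted SANS curve.

    Parameters
    ----------
    curve : ScatteringCurve
        Background-subtracted SANS curve.
    q_window : (float, float)
        Fit window in nm^-1 (default 0.31-1.14, the thin-sheet regime of
        ~4 nm bilayers).
    r2_threshold : float
        Goodness gate; results below it are flagged non-conforming, not
        rejected.
    weighted : bool
        When True and the curve carries per-point sigma, perform weighted
        least squares with weights 1/var(ln(I q^2)) = (I/sigma)^2.
    """

    def __init__(self, curve: ScatteringCurve,
                 q_window: Tuple[float, float] = (0.31, 1.14),
                 r2_threshold: float = 0.993,
                 weighted: bool = False):
        self.curve = curve
        self.q_window = (float(q_window[0]), float(q_window[1]))
        self.r2_threshold = float(r2_threshold)
        self.weighted = bool(weighted)
        if self.weighted and curve.sigma is None:
            raise ValueError("weighted fit requested but curve has no sigma")

    def fit(self) -> KratkyPorodResult:
        q_lo, q_hi = self.q_window
        mask = (self.curve.q >= q_lo) & (self.curve.q <= q_hi)
        n = int(mask.sum())
        if n < 6:
            raise ValueError(
                f"only {n} points in q window [{q_lo}, {q_hi}] (need >= 6)")
        q = self.curve.q[mask]
        I = self.curve.I[mask]
        if np.any(I <= 0):
            raise ValueError(
                "non-positive intensities inside the fit window (background "
                "over-subtraction?); refusing to drop points silently")
        x = q * q
        y = np.log(I * x)
        if self.weighted:
            sd_y = self.curve.sigma[mask] / I
            w = 1.0 / sd_y ** 2
        else:
            w = np.ones_like(x)

        # (weighted) least squares with analytic covariance
        W = np.sum(w)
        xbar = np.sum(w * x) / W
        ybar = np.sum(w * y) / W
        sxx = np.sum(w * (x - xbar) ** 2)
        sxy = np.sum(w * (x - xbar) * (y - ybar))
        slope = sxy / sxx
        intercept = ybar - slope * xbar
        resid = y - (intercept + slope * x)
        dof = n - 2
        s2 = np.sum(w * resid ** 2) / dof
        if self.curve.sigma is not None and np.all(self.curve.sigma[mask] > 0):
            # propagate the known per-point variances var(ln I q^2)
            # = (sigma/I)^2 through the estimator; the counting noise is
            # heteroscedastic in log space, so residual-based errors would
            # understate the slope uncertainty
            var_y = (self.curve.sigma[mask] / I) ** 2
            c_slope = w * (x - xbar) / sxx
            c_int = w / W - xbar * c_slope
            slope_sd = float(np.sqrt(np.sum(c_slope ** 2 * var_y)))
            intercept_sd = float(np.sqrt(np.sum(c_int ** 2 * var_y)))
        else:
            slope_sd = float(np.sqrt(s2 / sxx))
            intercept_sd = float(np.sqrt(s2 * (1.0 / W + xbar ** 2 / sxx)))
        syy = np.sum(w * (y - ybar) ** 2)
        r2 = float(sxy ** 2 / (sxx * syy)) if syy > 0 else 1.0

        if slope >= 0:
            raise ValueError(
                f"non-negative Kratky-Porod slope ({slope:.4g}); no "
                "thin-sheet regime in the fitted window")
        Rg = float(np.sqrt(-slope))
        Rg_sd = slope_sd / (2.0 * Rg)
        return KratkyPorodResult(
            slope=float(slope), intercept=float(intercept),
            slope_sd=slope_sd, intercept_sd=intercept_sd,
            r2=min(r2, 1.0), Rg=Rg, Rg_sd=Rg_sd,
            d_g=SQRT12 * Rg, d_g_sd=SQRT12 * Rg_sd,
            q_window=self.q_window, n_points=n,
            q_max_used=float(q[-1]),
            conforming=bool(r2 >= self.r2_threshold),
            r2_threshold=self.r2_threshold,
            weighted=self.weighted,
            q2=x, log_iq2=y,
        )


def kratky_porod_fit(curve: ScatteringCurve,
                     q_window: Tuple[float, float] = (0.31, 1.14),
                     **kwargs) -> KratkyPorodResult:
    """Convenience wrapper: build a :class:`KratkyPorod` model and fit it."""
    return KratkyPorod(curve, q_window=q_window, **kwargs).fit()


@dataclass
class GuinierDiagnostic:
    """Validity report for the thin-sheet Guinier approximation."""

    q_max: float
    Rg: float
    q_Rg_max: float
    exceeds_guinier_limit: bool

    def summary(self) -> str:
        status = ("exceeds the Guinier validity limit q*Rg < 1"
                  if self.exceeds_guinier_limit else
                  "within the Guinier validity limit q*Rg < 1")
        return (f"max(q)*Rg = {self.q_Rg_max:.4f} "
                f"(q_max = {self.q_max:.3f} nm^-1, Rg = {self.Rg:.4f} nm): "
                f"{status}")


def guinier_validity(result: KratkyPorodResult) -> GuinierDiagnostic:
    """Report max(q)*Rg over the fitted window and flag q*Rg > 1."""
    q_rg = result.q_max_used * result.Rg
    return GuinierDiagnostic(
        q_max=result.q_max_used, Rg=result.Rg, q_Rg_max=q_rg,
        exceeds_guinier_limit=bool(q_rg > 1.0))
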