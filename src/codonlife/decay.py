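"""Pulse-chase decay fitting with cell-division dilution correction.

The fitted model is a single exponential over a background,

    I(t) = background + f0 * exp(-(k_deg + k_div) * t),

with t in hours and all parameters constrained non-negative.  ``k_div`` is the
cell-division (dilution) rate: label is lost both by degradation and by being
diluted across daughter cells, so the observable decay rate is the sum.  The
protein half-life is reported from the degradation rate alone,
t_half = ln 2 / k_deg, alongside the composite half-life ln 2 / (k_deg+k_div).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


@dataclass(frozen=True)
class DecayCurve:
    """One construct's pulse-chase time course (replicate means)."""

    construct: str
    times_h: np.ndarray
    intensities: np.ndarray  # arbitrary fluorescence units
    sem: np.ndarray | None = None
    n_replicates: int = 1

    def __post_init__(self):
        t = np.asarray(self.times_h, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "intensities", y)
        if self.sem is not None:
            object.__setattr__(self, "sem", np.asarray(self.sem, dtype=float))
        if t.size < 3:
            raise ValueError("decay curve needs at least 3 time points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time points must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("intensities must be finite")


@dataclass(frozen=True)
class DecayFit:
    """Kinetic parameters for one curve; rates per hour, half-lives in hours."""

    construct: str
    k_deg: float
    k_div: float
    f0: float
    background: float
    t_half: float  # ln2 / k_deg; inf when k_deg == 0
    t_half_composite: float  # ln2 / (k_deg + k_div)
    fit_r2: float
    converged: bool
    k_div_fitted: bool
    message: str = ""

    def predict(self, times_h: np.ndarray) -> np.ndarray:
        t = np.asarray(times_h, dtype=float)
        return self.background + self.f0 * np.exp(-(self.k_deg + self.k_div) * t)


def _model_fixed_kdiv(t, k_deg, f0, background, k_div):
    return background + f0 * np.exp(-(k_deg + k_div) * t)


def _r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else math.nan
    return 1.0 - ss_res / ss_tot


def _initial_guess(curve: DecayCurve) -> tuple[float, float, float]:
    y = curve.intensities
    t = curve.times_h
    background = max(float(y.min()), 0.0)
    f0 = max(float(y[0] - background), 1e-9)
    # log-linear slope on background-subtracted positive points
    pos = y - background > f0 * 1e-3
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(y[pos] - background + 1e-12), 1)[0]
        k0 = max(-float(slope), 1e-6)
    else:
        k0 = 0.05
    return k0, f0, background


def fit_decay(curve: DecayCurve, k_div: float | str = 0.0,
              background: float | str = "fit",
              weight_by_sem: bool = False) -> DecayFit:
    """Fit the exponential decay model to one pulse-chase curve.

    Parameters
    ----------
    curve : DecayCurve
    k_div : float or "fit"
        Known division rate per hour, or ``"fit"`` to estimate it jointly
        (requires >= 5 time points; note that a single curve only constrains
        the sum k_deg + k_div, so the split is poorly identified).
    background : float or "fit"
        Known background intensity (e.g. measured on untransfected control
        wells), or ``"fit"`` to estimate it.  Fixing a measured background
        considerably stabilises slow-decay fits over a finite chase window.
    weight_by_sem : bool
        Weight residuals by 1/sem when per-point s.e.m. values are available.

    Non-convergence is flagged on the returned :class:`DecayFit`, not raised.
    """
    fit_kdiv = isinstance(k_div, str)
    if fit_kdiv:
        if k_div != "fit":
            raise ValueError(f"k_div must be a rate or 'fit', got {k_div!r}")
        if curve.times_h.size < 5:
            raise ValueError("fitting k_div requires at least 5 time points")
    elif k_div < 0:
        raise ValueError("k_div must be non-negative")
    fit_bg = isinstance(background, str)
    if fit_bg and background != "fit":
        raise ValueError(f"background must be an intensity or 'fit', got {background!r}")
    if not fit_bg and background < 0:
        raise ValueError("background must be non-negative")

    t, y = curve.times_h, curve.intensities
    sigma = None
    if weight_by_sem and curve.sem is not None and np.all(curve.sem > 0):
        sigma = curve.sem
    k0, f00, bg0 = _initial_guess(curve)
    if not fit_bg:
        bg0 = float(background)
        f00 = max(float(y[0] - bg0), 1e-9)

    try:
        free_bg = [bg0] if fit_bg else []

        def model(t, k_deg, f0, *rest):
            rest = list(rest)
            kdiv_ = rest.pop(0) if fit_kdiv else float(k_div)
            bg_ = rest.pop(0) if fit_bg else float(background)
            return _model_fixed_kdiv(t, k_deg, f0, bg_, kdiv_)

        p0 = [k0 / 2 if fit_kdiv else max(k0 - float(k_div), 1e-6), f00] + \
            ([k0 / 2] if fit_kdiv else []) + free_bg
        n_par = len(p0)
        popt, _ = curve_fit(model, t, y, p0=p0, bounds=([0] * n_par, [np.inf] * n_par),
                            sigma=sigma, maxfev=20000)
        rest = list(popt[2:])
        k_deg_hat, f0_hat = popt[0], popt[1]
        k_div_hat = rest.pop(0) if fit_kdiv else float(k_div)
        bg_hat = rest.pop(0) if fit_bg else float(background)
        converged, message = True, ""
    except RuntimeError as exc:  # pragma: no cover - optimizer failure path
        return DecayFit(curve.construct, math.nan, float(k_div) if not fit_kdiv else math.nan,
                        math.nan, math.nan, math.nan, math.nan, math.nan,
                        converged=False, k_div_fitted=fit_kdiv, message=str(exc))

    if k_deg_hat < 1e-12:  # numerically at the non-negativity boundary
        k_deg_hat = 0.0
    predicted = _model_fixed_kdiv(t, k_deg_hat, f0_hat, bg_hat, k_div_hat)
    composite = k_deg_hat + k_div_hat
    return DecayFit(
        construct=curve.construct,
        k_deg=float(k_deg_hat),
        k_div=float(k_div_hat),
        f0=float(f0_hat),
        background=float(bg_hat),
        t_half=math.inf if k_deg_hat <= 0 else math.log(2) / k_deg_hat,
        t_half_composite=math.inf if composite <= 0 else math.log(2) / composite,
        fit_r2=_r_squared(y, predicted),
        converged=converged,
        k_div_fitted=fit_kdiv,
        message=message,
    )


def dilution_line(k_div: float, times_h: np.ndarray) -> np.ndarray:
    """Percent of label remaining if lost only to division dilution."""
    if k_div < 0:
        raise ValueError("k_div must be non-negative")
    return 100.0 * np.exp(-k_div * np.asarray(times_h, dtype=float))


def time0_abundance(curve: DecayCurve, fit: DecayFit | None = None) -> tuple[float, str]:
    """Initial abundance: the measured t=0 intensity if present, else the
    fitted plateau background + f0.  Returns (value, basis)."""
    if curve.times_h[0] == 0:
        return float(curve.intensities[0]), "measured"
    if fit is not None and fit.converged:
        return fit.background + fit.f0, "fitted"
    raise ValueError("no t=0 point and no converged fit available")
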