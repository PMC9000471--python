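"""Feature extraction from TGA/DSC thermograms of freeze-dried silk.

Extracted features follow the conventions of simultaneous thermal
analysis at 10 °C min⁻¹ over 20–350 °C:

- water content: TGA mass-% lost between 20 and 140 °C (adsorbed and
  strongly bound water);
- extrapolated onset temperature T_o: intersection of the pre-event
  baseline tangent with the tangent at the maximum-slope point;
- peak temperature T_dec / T_d: derivative-mass-loss extremum (TGA) or
  signal extremum of the stated sense (DSC);
- desorption enthalpy ΔH_d: time-domain integral of the
  baseline-subtracted endotherm, normalized to the dry (corrected) mass;
  negative = endothermic.

Temperatures stay in °C throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "Thermogram",
    "ThermalFeatures",
    "EventNotFoundError",
    "DEFAULT_SCAN_RATE",
    "water_content",
    "extrapolated_onset",
    "peak_temperature",
    "desorption_enthalpy",
    "glass_transition",
]

#: Heating rate in °C min⁻¹ used to convert the temperature axis to time.
DEFAULT_SCAN_RATE = 10.0


class EventNotFoundError(ValueError):
    """No thermal event (slope or signal extremum) in the given window."""


@dataclass(frozen=True)
class Thermogram:
    """Temperature-indexed signal: mass % for ``kind="tga"``, specific
    heat flow (W g⁻¹) for ``kind="dsc"``."""

    temperature: np.ndarray
    signal: np.ndarray
    kind: str = "tga"

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.ndim != 1 or t.shape != s.shape:
            raise ValueError("temperature and signal must be equal-length 1-D")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if self.kind not in ("tga", "dsc"):
            raise ValueError(f"kind must be 'tga' or 'dsc', got {self.kind!r}")
        if self.kind == "tga" and (np.any(s <= 0) or np.any(s > 100 + 1e-9)):
            raise ValueError("TGA mass % must lie in (0, 100]")
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "signal", s)

    def restrict(self, lo: float, hi: float) -> "Thermogram":
        sel = (self.temperature >= lo) & (self.temperature <= hi)
        return Thermogram(self.temperature[sel], self.signal[sel], self.kind)


@dataclass(frozen=True)
class ThermalFeatures:
    """Extracted events; fields are None when not measured."""

    water_content: float | None = None  # % w/w
    t_d: float | None = None            # desorption peak, °C
    dh_d: float | None = None           # desorption enthalpy, J g⁻¹ (endo < 0)
    t_o: float | None = None            # extrapolated onset, °C
    t_dec: float | None = None          # decomposition peak, °C
    t_g: float | None = None            # glass transition midpoint, °C


def water_content(
    tga: Thermogram, window: tuple[float, float] = (20.0, 140.0)
) -> float:
    """Mass % lost across the window (linear interpolation at bounds)."""
    lo, hi = window
    t = tga.temperature
    if lo < t[0] or hi > t[-1]:
        raise ValueError(f"window {window} outside the {t[0]}-{t[-1]} °C grid")
    m_lo = float(np.interp(lo, t, tga.signal))
    m_hi = float(np.interp(hi, t, tga.signal))
    return m_lo - m_hi


def _smoothed_derivative(
    t: np.ndarray, y: np.ndarray, window: int = 11
) -> np.ndarray:
    """dY/dT after an 11-point quadratic pre-smoother (configurable)."""
    if y.size >= window:
        y = savgol_filter(y, window, 2)
    return np.gradient(y, t)


def _refine_extremum(
    t: np.ndarray, y: np.ndarray, idx: int, span: float = 6.0
) -> float:
    """Quadratic-interpolation refinement of a grid extremum location,
    fit over ±``span`` °C so grid-scale noise averages out."""
    step = float(np.median(np.diff(t))) if t.size > 1 else 1.0
    half = max(int(round(span / step)), 1)
    lo, hi = max(idx - half, 0), min(idx + half + 1, t.size)
    if hi - lo < 3:
        return float(t[idx])
    coeffs = np.polyfit(t[lo:hi], y[lo:hi], 2)
    if coeffs[0] == 0:
        return float(t[idx])
    t_star = -coeffs[1] / (2 * coeffs[0])
    if not t[lo] <= t_star <= t[hi - 1]:
        return float(t[idx])
    return float(t_star)


def extrapolated_onset(
    tg: Thermogram,
    event_window: tuple[float, float],
    baseline_fraction: float = 0.25,
    smooth_window: int = 11,
) -> float:
    """Extrapolated onset: intersection of the pre-event baseline tangent
    (least-squares line over the first ``baseline_fraction`` of the
    window) with the tangent at the maximum-|slope| point."""
    seg = tg.restrict(*event_window)
    t, y = seg.temperature, seg.signal
    if t.size < max(smooth_window, 8):
        raise EventNotFoundError("window too short for onset analysis")
    n_base = max(int(baseline_fraction * t.size), 3)
    b_slope, b_icept = np.polyfit(t[:n_base], y[:n_base], 1)
    ys = savgol_filter(y, smooth_window, 2) if y.size >= smooth_window else y
    deriv = np.gradient(ys, t)
    excess = np.abs(deriv - b_slope)
    idx = int(np.argmax(excess))
    scale = (np.max(y) - np.min(y)) / (t[-1] - t[0])
    if idx <= n_base or idx >= t.size - 1 or excess[idx] < 1e-6 * max(scale, 1e-30):
        raise EventNotFoundError(
            f"no slope event found inside window {event_window}"
        )
    # refine the inflection location, then take the tangent as a short
    # central secant of the smoothed signal there — the smoothed-gradient
    # value at the grid extremum is biased low, which shifts the onset
    t_star = _refine_extremum(t, np.sign(deriv[idx] - b_slope) * excess, idx)
    delta = max(2.0 * float(np.median(np.diff(t))), 1.0)
    lo_t = max(t_star - delta, t[0])
    hi_t = min(t_star + delta, t[-1])
    m_star = float(
        (np.interp(hi_t, t, ys) - np.interp(lo_t, t, ys)) / (hi_t - lo_t)
    )
    if m_star == b_slope:
        raise EventNotFoundError("event tangent parallel to baseline")
    y_star = float(np.interp(t_star, t, ys))
    return float((y_star - m_star * t_star - b_icept) / (b_slope - m_star))


def peak_temperature(
    tg: Thermogram,
    event_window: tuple[float, float],
    sense: str = "auto",
    smooth_window: int = 11,
) -> float:
    """Peak temperature of a thermal event.

    TGA (``sense="mass-loss"`` or ``"auto"``): temperature of the
    derivative-mass-loss extremum.  DSC: temperature of the signal
    extremum, ``sense="endo"`` (minimum, endotherm-negative convention)
    or ``"exo"`` (maximum).  The grid extremum is refined by local
    quadratic interpolation.
    """
    seg = tg.restrict(*event_window)
    t, y = seg.temperature, seg.signal
    if t.size < 5:
        raise EventNotFoundError("window too short for peak analysis")
    if tg.kind == "tga" and sense in ("auto", "mass-loss"):
        curve = _smoothed_derivative(t, y, smooth_window)
        idx = int(np.argmin(curve))  # fastest mass loss
        curve_for_fit = curve
    else:
        if sense == "auto":
            raise ValueError("DSC peaks need sense='endo' or 'exo'")
        if sense == "endo":
            idx = int(np.argmin(y))
        elif sense == "exo":
            idx = int(np.argmax(y))
        else:
            raise ValueError(f"unknown sense {sense!r}")
        curve_for_fit = y
    if idx == 0 or idx == t.size - 1:
        raise EventNotFoundError(
            f"no interior extremum in window {event_window} (monotone signal?)"
        )
    return _refine_extremum(t, curve_for_fit, idx)


def desorption_enthalpy(
    dsc: Thermogram,
    window: tuple[float, float],
    dry_mass_fraction: float = 1.0,
    scan_rate: float = DEFAULT_SCAN_RATE,
    baseline: str = "linear",
    anchor_margin: float = 2.0,
) -> float:
    """Desorption enthalpy in J per gram of dry mass.

    The heat-flow signal (W per initial gram) is baseline-subtracted
    (straight line between the window endpoints by default; each anchor
    level is the signal average over ``anchor_margin`` °C inside the
    endpoint, so single-sample noise does not tilt the baseline),
    integrated over time using the scan rate (°C min⁻¹) to convert the
    temperature axis, and divided by ``dry_mass_fraction`` to normalize
    to the corrected (dry) mass.  Sign is preserved: endotherms are
    negative.
    """
    if not 0 < dry_mass_fraction <= 1:
        raise ValueError("dry_mass_fraction must be in (0, 1]")
    if dsc.kind != "dsc":
        raise ValueError("desorption_enthalpy needs a DSC thermogram")
    seg = dsc.restrict(*window)
    t, y = seg.temperature, seg.signal
    if t.size < 3:
        raise ValueError("window too short for integration")
    y0 = float(y[t <= t[0] + anchor_margin].mean())
    y1 = float(y[t >= t[-1] - anchor_margin].mean())
    if baseline == "linear":
        base = np.interp(t, [t[0], t[-1]], [y0, y1])
    elif baseline == "sigmoidal":
        # endpoint levels blended by the normalized cumulative event area
        lin = np.interp(t, [t[0], t[-1]], [y0, y1])
        dev = np.abs(y - lin)
        cum = np.concatenate([[0.0], np.cumsum((dev[1:] + dev[:-1]) / 2 * np.diff(t))])
        frac = cum / cum[-1] if cum[-1] > 0 else np.linspace(0, 1, t.size)
        base = y0 + (y1 - y0) * frac
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    rate_c_per_s = scan_rate / 60.0
    area = float(np.trapezoid(y - base, t)) / rate_c_per_s  # J g⁻¹ (initial mass)
    return area / dry_mass_fraction


def glass_transition(
    dsc: Thermogram, window: tuple[float, float], smooth_window: int = 11
) -> float:
    """Half-height midpoint of a heat-flow step (experimental: reported
    inconsistently for these materials; use with care)."""
    seg = dsc.restrict(*window)
    t, y = seg.temperature, seg.signal
    if t.size < max(smooth_window, 5):
        raise EventNotFoundError("window too short for Tg analysis")
    deriv = _smoothed_derivative(t, y, smooth_window)
    idx = int(np.argmax(np.abs(deriv)))
    if idx == 0 or idx == t.size - 1:
        raise EventNotFoundError("no heat-flow step in window")
    half = (y[0] + y[-1]) / 2.0
    sign = 1.0 if y[-1] >= y[0] else -1.0
    crossings = np.flatnonzero(np.diff(np.sign(sign * (y - half))) > 0)
    if crossings.size == 0:
        raise EventNotFoundError("no half-height crossing in window")
    i = int(crossings[0])
    return float(np.interp(half, [y[i], y[i + 1]][:: int(sign)], [t[i], t[i + 1]][:: int(sign)]))
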