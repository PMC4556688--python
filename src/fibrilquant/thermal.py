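"""Transition-temperature extraction from DSC thermograms.

A corneal stroma thermogram scanned from 10 to 95 C shows a single broad
endotherm from the collagen helix-coil transition.  The extraction here is a
linear baseline subtraction (fit to both tails), moving-average smoothing,
global-extremum search on the magnitude of the corrected signal (so
endotherm-up and endotherm-down conventions both work), and sub-grid
refinement by parabolic interpolation through the extremum and its neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "Thermogram",
    "TransitionResult",
    "NoPeakError",
    "subtract_linear_baseline",
    "find_transition_temperature",
]


class NoPeakError(RuntimeError):
    """Raised when no transition rises clearly above the tail noise."""


@dataclass(frozen=True)
class Thermogram:
    """A DSC curve: strictly increasing temperatures (C) and heat flow."""

    temperature_C: np.ndarray
    heat_flow: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature_C, dtype=float)
        y = np.asarray(self.heat_flow, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValueError("temperature and heat flow must be 1-D and equal length")
        if len(t) < 20:
            raise ValueError("thermogram needs at least 20 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if t[0] < 10.0 - 1e-9 or t[-1] > 95.0 + 1e-9:
            raise ValueError("temperatures must lie within [10, 95] C")
        object.__setattr__(self, "temperature_C", t)
        object.__setattr__(self, "heat_flow", y)

    def __len__(self) -> int:
        return len(self.temperature_C)


@dataclass(frozen=True)
class TransitionResult:
    transition_temp_C: float
    peak_height: float
    baseline_params: tuple[float, float]  # (slope, intercept)


def subtract_linear_baseline(
    curve: Thermogram, fit_fraction: float = 0.1
) -> tuple[Thermogram, tuple[float, float]]:
    """Fit a line to the first and last ``fit_fraction`` of points; subtract it.

    The transition occupies the middle of the scan, so both tails are
    baseline; a least-squares line through them removes instrument drift.
    Returns the corrected curve and (slope, intercept).

    Raises ``ValueError`` if either fit window has fewer than 3 points.
    """
    if not (0.0 < fit_fraction <= 0.4):
        raise ValueError("fit_fraction must lie in (0, 0.4]")
    t, y = curve.temperature_C, curve.heat_flow
    k = int(np.ceil(fit_fraction * len(t)))
    if k < 3:
        raise ValueError(f"fit windows of {k} points are degenerate (< 3)")
    tt = np.concatenate([t[:k], t[-k:]])
    yy = np.concatenate([y[:k], y[-k:]])
    slope, intercept = np.polyfit(tt, yy, 1)
    corrected = Thermogram(
        temperature_C=t,
        heat_flow=y - (slope * t + intercept),
        sample_id=curve.sample_id,
    )
    return corrected, (float(slope), float(intercept))


def find_transition_temperature(
    curve: Thermogram,
    smoothing_window: int = 5,
    fit_fraction: float = 0.1,
) -> TransitionResult:
    """Locate the denaturation peak of a (raw or corrected) thermogram.

    Baseline-corrects, smooths with an odd moving average, takes the global
    extremum of the magnitude of the corrected signal (first occurrence, i.e.
    the lowest temperature, on exact ties), and refines the peak position with
    a parabola through the extremum sample and its two neighbors.

    Raises
    ------
    NoPeakError
        If the extremum magnitude is below 3x the tail noise estimate
        (standard deviation of the residual corrected signal in the fit
        windows).
    ValueError
        If ``smoothing_window`` is even or nonpositive.
    """
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be a positive odd integer")
    corrected, baseline = subtract_linear_baseline(curve, fit_fraction)
    t = corrected.temperature_C
    y = corrected.heat_flow
    if smoothing_window > 1:
        y = ndimage.uniform_filter1d(y, smoothing_window, mode="nearest")

    i = int(np.argmax(np.abs(y)))
    sign = 1.0 if y[i] >= 0 else -1.0
    s = y * sign  # peak-up by construction

    # noise estimated from the *unsmoothed* corrected tails: smoothing leaves a
    # broad peak almost untouched but shrinks noise by ~sqrt(window), so the
    # raw-tail scale is the conservative reference for "no peak here"
    k = int(np.ceil(fit_fraction * len(t)))
    raw = corrected.heat_flow
    noise = float(np.std(np.concatenate([raw[:k], raw[-k:]])))
    if s[i] < 3.0 * noise + 1e-12:
        raise NoPeakError(
            f"extremum magnitude {s[i]:.3g} below 3x tail noise {noise:.3g}"
        )

    if 0 < i < len(t) - 1:
        # quadratic through the three samples; vertex is the refined peak
        coeffs = np.polyfit(t[i - 1 : i + 2], s[i - 1 : i + 2], 2)
        if coeffs[0] < 0:
            peak_t = float(-coeffs[1] / (2.0 * coeffs[0]))
            peak_t = float(np.clip(peak_t, t[i - 1], t[i + 1]))
            peak_h = float(np.polyval(coeffs, peak_t))
        else:  # degenerate (flat or concave-up triplet): keep the sample
            peak_t, peak_h = float(t[i]), float(s[i])
    else:
        peak_t, peak_h = float(t[i]), float(s[i])
    return TransitionResult(
        transition_temp_C=peak_t,
        peak_height=peak_h * sign,
        baseline_params=baseline,
    )
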