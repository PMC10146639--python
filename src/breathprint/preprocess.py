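"""Raw trace -> breath print: smoothing, baseline correction, dR/R.

The response of each sensor is the relative resistance change

    dR/R = (R_max - R_0) / R_0

with ``R_0`` the mean (smoothed) resistance over the baseline window and
``R_max`` the maximum smoothed, baseline-corrected resistance over the
exposure window.  Traces are Savitzky-Golay filtered first; a linear drift
estimated on the baseline window is then subtracted over the whole trace.

Smoothing defaults (window 11 samples, cubic polynomial) are deliberately
mild so the exposure plateau is preserved; both are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .containers import (
    N_SENSORS,
    BreathPrint,
    BreathPrintSet,
    RawSensorTrace,
    mask_from_disabled,
)

__all__ = [
    "PreprocessSettings",
    "savitzky_golay",
    "baseline_correct",
    "sensor_response",
    "make_breathprints",
]


@dataclass(frozen=True)
class PreprocessSettings:
    sg_window: int = 11
    sg_polyorder: int = 3
    disabled_sensors: tuple[int, ...] = ()

    def validate(self) -> None:
        _check_sg_params(self.sg_window, self.sg_polyorder)
        mask_from_disabled(self.disabled_sensors)


def _check_sg_params(window: int, polyorder: int) -> None:
    if window % 2 == 0:
        raise ValueError(f"Savitzky-Golay window must be odd; got {window}")
    if window <= polyorder:
        raise ValueError(
            f"Savitzky-Golay window ({window}) must exceed polyorder ({polyorder})"
        )
    if polyorder < 0:
        raise ValueError("polyorder must be >= 0")


def savitzky_golay(series: Sequence[float], window: int = 11, polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing with truncated-window edge handling.

    Interior points are the standard local least-squares polynomial fit.
    Within half a window of either end the polynomial is refit per point on
    the window truncated at the boundary (degree reduced if the truncated
    window holds fewer than ``polyorder + 1`` points) and evaluated at that
    point.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    _check_sg_params(window, polyorder)
    n = x.size
    if n < window:
        raise ValueError(f"series length {n} shorter than window {window}")
    out = savgol_filter(x, window_length=window, polyorder=polyorder, mode="interp")
    half = window // 2
    for i in list(range(half)) + list(range(n - half, n)):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        deg = min(polyorder, hi - lo - 1)
        t = np.arange(lo, hi, dtype=float)
        coef = np.polynomial.polynomial.polyfit(t - i, x[lo:hi], deg)
        out[i] = coef[0]  # polynomial evaluated at the centred origin
    return out


def baseline_correct(
    trace: RawSensorTrace, sg_window: int = 11, sg_polyorder: int = 3
) -> tuple[RawSensorTrace, np.ndarray]:
    """Smooth each sensor, remove linear baseline drift, return (trace, R0).

    The drift line is fit on the (smoothed) baseline window and extrapolated
    over the full trace; after subtraction the corrected baseline mean equals
    R0 for every sensor.
    """
    b0, b1 = trace.baseline_window
    if b1 - b0 < 1:
        raise ValueError("empty baseline window")
    if (b1 - b0) < sg_window or (trace.exposure_window[1] - trace.exposure_window[0]) < sg_window:
        raise ValueError(
            f"windows must span at least the smoothing window ({sg_window} points)"
        )
    t = trace.time_axis
    tb = t[b0:b1]
    corrected = np.empty_like(trace.sensor_values)
    r0 = np.empty(N_SENSORS)
    for s in range(N_SENSORS):
        smooth = savitzky_golay(trace.sensor_values[s], sg_window, sg_polyorder)
        base = smooth[b0:b1]
        r0[s] = float(base.mean())
        if tb.size >= 2:
            slope, intercept = np.polyfit(tb, base, 1)
        else:
            slope, intercept = 0.0, r0[s]
        corrected[s] = smooth - (slope * t + intercept) + r0[s]
    new_trace = replace(trace, sensor_values=_positive_guard(corrected))
    return new_trace, r0


def _positive_guard(values: np.ndarray) -> np.ndarray:
    # RawSensorTrace enforces positivity; baseline correction of a valid
    # physical trace keeps resistances positive, but clip defensively at a
    # tiny floor so pathological synthetic inputs still flow through.
    floor = np.finfo(float).tiny
    return np.maximum(values, floor)


def sensor_response(trace: RawSensorTrace, r0: np.ndarray | None = None) -> np.ndarray:
    """Per-sensor dR/R over the exposure window of a corrected trace.

    If ``r0`` is not given it is recomputed as the baseline-window mean of the
    (already smoothed/corrected) trace.  Negative responses are kept: the
    formula is signed and resistance may fall on exposure.
    """
    b0, b1 = trace.baseline_window
    e0, e1 = trace.exposure_window
    if r0 is None:
        r0 = trace.sensor_values[:, b0:b1].mean(axis=1)
    r0 = np.asarray(r0, dtype=float)
    if np.any(r0 <= 0):
        bad = np.flatnonzero(r0 <= 0) + 1
        raise ValueError(f"non-physical baseline resistance R0 <= 0 for sensors {bad.tolist()}")
    r_max = trace.sensor_values[:, e0:e1].max(axis=1)
    return (r_max - r0) / r0


def make_breathprints(
    traces: Iterable[RawSensorTrace],
    settings: PreprocessSettings | None = None,
) -> BreathPrintSet:
    """Full preprocessing pipeline: smooth -> baseline-correct -> dR/R.

    Preprocessing is strictly per-sample: each print depends only on its own
    trace.  Sensors listed in ``settings.disabled_sensors`` are flagged
    inactive in the mask but their responses are still computed and carried.
    """
    settings = settings or PreprocessSettings()
    settings.validate()
    mask = mask_from_disabled(settings.disabled_sensors)
    prints: list[BreathPrint] = []
    seen: set[str] = set()
    for trace in traces:
        if trace.sample_id in seen:
            raise ValueError(f"duplicate sample_id {trace.sample_id!r}")
        seen.add(trace.sample_id)
        corrected, r0 = baseline_correct(trace, settings.sg_window, settings.sg_polyorder)
        response = sensor_response(corrected, r0)
        prints.append(
            BreathPrint(
                sample_id=trace.sample_id,
                subject_id=trace.subject_id or trace.sample_id,
                group=trace.group,
                response=response,
                mask=mask.copy(),
            )
        )
    return BreathPrintSet(prints)
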