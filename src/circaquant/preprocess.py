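"""Spike filtering, rolling-mean smoothing, detrending and noise (RMSE) estimation.

The cleaning chain for a luminometer trace is: remove aberrant single
counts (readings deviating from a 2-h rolling mean by more than 8x the
trace's mean deviation), subtract a 24-h rolling mean to detrend, and
smooth with a 2-h rolling mean for peak calling.  The trace RMSE — the
root-mean-square difference between the detrended trace and its 2-h
smoothed version — is the per-trace noise scale used to express cycle
amplitudes in dimensionless units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Trace

__all__ = [
    "rolling_mean",
    "filter_aberrant",
    "detrend",
    "trace_rmse",
    "FilterReport",
]


def _window_samples(window_h: float, dt_h: float) -> int:
    """Odd sample count for a centered window of half-width window_h/2.

    All samples within +-window_h/2 of the center are included (closed
    interval), so a 2-h window at 10-min sampling spans 13 samples.
    """
    if window_h <= 0:
        raise ValueError("window_h must be positive")
    if dt_h <= 0:
        raise ValueError("sampling interval must be positive")
    half = int(np.floor(window_h / (2.0 * dt_h) + 1e-9))
    return 2 * half + 1


def rolling_mean(trace: Trace, window_h: float) -> Trace:
    """Centered moving average with edge truncation.

    The window shrinks at both ends of the trace (no padding: padding
    would invent data at the boundaries of a finite recording).  Output
    length equals input length and the time axis is preserved.
    """
    dt = trace.dt_h
    if window_h < dt:
        raise ValueError(
            f"window of {window_h} h is shorter than one sample interval ({dt} h)"
        )
    w = _window_samples(window_h, dt)
    sm = (
        pd.Series(trace.value)
        .rolling(window=w, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return trace.replace(value=sm, kind="smoothed")


@dataclass
class FilterReport:
    """What the aberrant-count filter did to one trace."""

    removed_indices: np.ndarray
    mean_deviation: float
    threshold: float  # = k * mean_deviation
    k: float
    window_h: float
    slice_id: str = ""

    @property
    def n_removed(self) -> int:
        return len(self.removed_indices)


def filter_aberrant(
    trace: Trace,
    window_h: float = 2.0,
    k: float = 8.0,
    deviation: str = "mean_abs",
) -> tuple[Trace, FilterReport]:
    """Remove aberrant single counts and patch them by linear interpolation.

    A reading is aberrant when it deviates from the ``window_h`` rolling
    mean of the trace by more than ``k`` times the trace's mean deviation.
    Removed points are replaced by linear interpolation between surviving
    neighbours (keeping the uniform grid required by rolling windows) and
    flagged in ``meta['interpolated']``.

    Parameters
    ----------
    deviation : {"mean_abs", "rms"}
        How "mean deviation for that trace" is computed: mean absolute
        deviation of (raw - smoothed) (default) or its root mean square.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    smoothed = rolling_mean(trace, window_h)
    dev = np.abs(trace.value - smoothed.value)
    if deviation == "mean_abs":
        scale = float(dev.mean())
    elif deviation == "rms":
        scale = float(np.sqrt(np.mean(dev**2)))
    else:
        raise ValueError("deviation must be 'mean_abs' or 'rms'")

    threshold = k * scale
    if scale == 0.0:  # constant trace: nothing deviates
        flagged = np.zeros(len(trace), dtype=bool)
    else:
        flagged = dev > threshold
    if flagged.all():
        raise ValueError(
            f"all {len(trace)} points flagged as aberrant (slice "
            f"{trace.slice_id!r}); trace is pathological"
        )

    value = trace.value.copy()
    if flagged.any():
        good = ~flagged
        value[flagged] = np.interp(
            trace.time_h[flagged], trace.time_h[good], value[good]
        )
    prior = np.asarray(
        trace.meta.get("interpolated", np.zeros(len(trace), dtype=bool)), dtype=bool
    )
    out = trace.replace(value=value, kind="raw", interpolated=prior | flagged)
    report = FilterReport(
        removed_indices=np.flatnonzero(flagged),
        mean_deviation=scale,
        threshold=threshold,
        k=k,
        window_h=window_h,
        slice_id=trace.slice_id,
    )
    return out, report


def detrend(trace: Trace, window_h: float = 24.0) -> Trace:
    """Subtract a ``window_h`` (default 24 h) rolling-mean baseline.

    A 24-h window removes slow baseline drift while leaving a ~24-h
    oscillation nearly untouched in the interior (the centered 24-h mean
    of a 24-h cosine is zero; of a linear ramp, the ramp itself).

    In the interior the baseline is the centered full-window rolling
    mean.  Within ``window_h/2`` of either end, where a centered window
    no longer covers a whole cycle, the truncated mean would leak the
    oscillation itself into the baseline and bias downstream period
    estimates; the baseline is instead extended by a linear fit to the
    adjacent ``window_h`` of interior baseline, which tracks a slow
    drift with negligible error over half a window.
    """
    if trace.duration_h < window_h:
        raise ValueError(
            f"trace spans {trace.duration_h:.1f} h, shorter than the "
            f"{window_h} h detrend window"
        )
    t, v = trace.time_h, trace.value
    w = _window_samples(window_h, trace.dt_h)
    baseline = (
        pd.Series(v).rolling(window=w, center=True, min_periods=w).mean().to_numpy()
    )
    valid = np.flatnonzero(np.isfinite(baseline))
    if len(valid) == 0:  # window_h equals the whole span: global mean
        baseline[:] = v.mean()
    else:
        lo, hi = valid[0], valid[-1]
        m = min(w, hi - lo + 1)
        if m >= 2 and lo > 0:
            coef = np.polyfit(t[lo:lo + m], baseline[lo:lo + m], 1)
            baseline[:lo] = np.polyval(coef, t[:lo])
        else:
            baseline[:lo] = baseline[lo]
        if m >= 2 and hi < len(v) - 1:
            coef = np.polyfit(t[hi - m + 1:hi + 1], baseline[hi - m + 1:hi + 1], 1)
            baseline[hi + 1:] = np.polyval(coef, t[hi + 1:])
        else:
            baseline[hi + 1:] = baseline[hi]
    return trace.replace(value=v - baseline, kind="detrended")


def trace_rmse(detrended: Trace, smooth_window_h: float = 2.0) -> float:
    """Per-trace noise scale.

    The square root of the mean squared difference between the detrended
    trace and its ``smooth_window_h`` rolling-mean smoothed version.  Zero
    iff the trace is already smooth at that scale.
    """
    if detrended.kind != "detrended":
        raise ValueError(f"expected a detrended trace, got kind={detrended.kind!r}")
    smoothed = rolling_mean(detrended, smooth_window_h)
    return float(np.sqrt(np.mean((detrended.value - smoothed.value) ** 2)))
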