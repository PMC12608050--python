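"""Cycle-wise peak/trough detection, RMSE-normalized amplitude, half-life fitting.

Peaks and troughs are sign changes in the slope of a sliding 8-h linear
fit of the 2-h smoothed trace; cycle amplitude is (peak - trough) divided
by the trace RMSE, giving a dimensionless signal-to-noise amplitude that
is comparable across slices with different absolute photon counts.
Post-cycloheximide decays are summarized by fitting y = e^(-t/k) to a
min-max-normalized 12-h segment; half-life = k * ln 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import Trace
from .preprocess import _window_samples

__all__ = [
    "CyclePeaks",
    "AmplitudeSeries",
    "HalfLifeFit",
    "sliding_slope",
    "find_peaks_troughs",
    "amplitude_per_cycle",
    "relative_amplitude",
    "estimate_half_life",
]


def sliding_slope(trace: Trace, fit_window_h: float = 8.0) -> np.ndarray:
    """Least-squares slope of a centered ``fit_window_h`` linear fit at each sample.

    Windows truncate at the trace edges (minimum 2 points).
    """
    t, v = trace.time_h, trace.value
    w = _window_samples(fit_window_h, trace.dt_h)
    roll = lambda x: pd.Series(x).rolling(w, center=True, min_periods=2).sum().to_numpy()
    n = pd.Series(np.ones_like(v)).rolling(w, center=True, min_periods=2).count().to_numpy()
    st, sv = roll(t), roll(v)
    stt, stv = roll(t * t), roll(t * v)
    denom = n * stt - st * st
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = (n * stv - st * sv) / denom
    slope[~np.isfinite(slope)] = 0.0
    return slope


@dataclass
class CyclePeaks:
    """Per-cycle peak/trough times and values for one trace.

    Cycles are indexed by peaks (1-based); each peak is paired with the
    next trough in time (the descending half-cycle).  A final peak with
    no following trough carries NaN trough fields.
    """

    cycle_index: np.ndarray
    peak_time_h: np.ndarray
    peak_value: np.ndarray
    trough_time_h: np.ndarray
    trough_value: np.ndarray
    slice_id: str = ""

    def __len__(self) -> int:
        return len(self.cycle_index)

    @property
    def n_complete(self) -> int:
        """Cycles that have both a peak and a following trough."""
        return int(np.sum(np.isfinite(self.trough_time_h)))


def _detect_extrema(t, v, slope, refine):
    """Sign changes of the slope -> list of (time, value, is_peak)."""
    tol = 1e-10 * max(1.0, float(np.max(np.abs(slope))))
    sign = np.zeros(len(slope), dtype=int)
    sign[slope > tol] = 1
    sign[slope < -tol] = -1
    nz = np.flatnonzero(sign)
    out = []
    for p, q in zip(nz[:-1], nz[1:]):
        if sign[p] == sign[q]:
            continue
        is_peak = sign[p] > 0
        if q == p + 1:
            if refine:
                # linear interpolation of the slope zero crossing
                t_star = t[p] + (t[q] - t[p]) * slope[p] / (slope[p] - slope[q])
            else:
                # crossing sample: the more extreme of the two, earlier on ties
                if is_peak:
                    t_star = t[p] if v[p] >= v[q] else t[q]
                else:
                    t_star = t[p] if v[p] <= v[q] else t[q]
        else:
            # midpoint of the zero-slope run, ties toward the earlier sample
            t_star = t[(p + q) // 2]
        out.append((float(t_star), float(np.interp(t_star, t, v)), is_peak))
    return out


def _enforce_spacing(ext, min_spacing_h):
    """Collapse noise doublets: same-type extrema closer than min_spacing_h."""
    ext = list(ext)
    changed = True
    while changed:
        changed = False
        for i in range(len(ext) - 2):
            (ta, va, ka), (_, _, _), (tc, vc, kc) = ext[i], ext[i + 1], ext[i + 2]
            if ka == kc and (tc - ta) < min_spacing_h:
                weaker = i if (va < vc) == ka else i + 2
                del ext[max(weaker, i + 1)], ext[min(weaker, i + 1)]
                changed = True
                break
    return ext


def find_peaks_troughs(
    smoothed: Trace,
    fit_window_h: float = 8.0,
    refine: bool = True,
    min_spacing_h: Optional[float] = None,
) -> CyclePeaks:
    """Locate cycle peaks and troughs by the sliding-slope sign-change rule.

    A +/- sign change of the sliding linear-fit slope marks a peak, a -/+
    change a trough.  With ``refine`` (default) the crossing is placed by
    linear interpolation between the two bracketing slope samples, giving
    sub-sample time resolution; zero-slope runs resolve to their midpoint.
    ``min_spacing_h`` optionally suppresses same-type extrema closer than
    that spacing (noise doublets), keeping the more extreme one.

    Values are read from the smoothed trace at the located times.
    A constant or monotone trace yields an empty result.
    """
    if smoothed.duration_h < fit_window_h:
        raise ValueError(
            f"trace spans {smoothed.duration_h:.1f} h, shorter than the "
            f"{fit_window_h} h fit window"
        )
    slope = sliding_slope(smoothed, fit_window_h)
    ext = _detect_extrema(smoothed.time_h, smoothed.value, slope, refine)
    if min_spacing_h is not None:
        ext = _enforce_spacing(ext, min_spacing_h)

    peaks = [(t, v) for t, v, is_peak in ext if is_peak]
    troughs = [(t, v) for t, v, is_peak in ext if not is_peak]
    n = len(peaks)
    pk_t = np.array([t for t, _ in peaks])
    pk_v = np.array([v for _, v in peaks])
    tr_t = np.full(n, np.nan)
    tr_v = np.full(n, np.nan)
    for i, (tp, _) in enumerate(peaks):
        following = [(t, v) for t, v in troughs if t > tp]
        if following:
            tr_t[i], tr_v[i] = following[0]
    return CyclePeaks(
        cycle_index=np.arange(1, n + 1),
        peak_time_h=pk_t,
        peak_value=pk_v,
        trough_time_h=tr_t,
        trough_value=tr_v,
        slice_id=smoothed.slice_id,
    )


@dataclass
class AmplitudeSeries:
    """Dimensionless per-cycle amplitudes, (peak - trough) / RMSE."""

    cycle_index: np.ndarray
    amplitude: np.ndarray
    rmse: float
    slice_id: str = ""

    @property
    def final_cycle(self) -> float:
        """Amplitude of the last complete cycle."""
        if len(self.amplitude) == 0:
            raise ValueError("no complete cycles")
        return float(self.amplitude[-1])


def amplitude_per_cycle(
    peaks: CyclePeaks, rmse: float, rmse_tol: float = 1e-12
) -> AmplitudeSeries:
    """Per-cycle amplitude normalized by the trace noise scale.

    Cycles lacking a following trough are dropped.  An RMSE at or below
    ``rmse_tol`` is rejected: a noise level indistinguishable from zero
    would make every amplitude infinite.
    """
    if not np.isfinite(rmse) or rmse <= rmse_tol:
        raise ValueError("noise level indistinguishable from zero (rmse <= tolerance)")
    complete = np.isfinite(peaks.trough_time_h)
    amps = (peaks.peak_value[complete] - peaks.trough_value[complete]) / rmse
    return AmplitudeSeries(
        cycle_index=peaks.cycle_index[complete],
        amplitude=amps,
        rmse=float(rmse),
        slice_id=peaks.slice_id,
    )


def relative_amplitude(
    final_cycle_amps: Mapping[str, float], control_ids: Sequence[str]
) -> dict:
    """Final-cycle amplitudes as percentages of the control-group mean.

    The control group mean is 100% by construction.
    """
    control_ids = list(control_ids)
    if not control_ids:
        raise ValueError("control group is empty")
    missing = [c for c in control_ids if c not in final_cycle_amps]
    if missing:
        raise KeyError(f"control ids missing from amplitudes: {missing}")
    ref = float(np.mean([final_cycle_amps[c] for c in control_ids]))
    if ref == 0:
        raise ValueError("control mean amplitude is zero")
    return {k: 100.0 * v / ref for k, v in final_cycle_amps.items()}


@dataclass
class HalfLifeFit:
    """Exponential-decay fit of a post-cycloheximide segment."""

    k_h: float                 # mean lifetime, hours
    half_life_h: float         # = k_h * ln 2, exactly
    residual_norm: float
    window: tuple              # (segment start_h, span_h)
    slice_id: str = ""


def estimate_half_life(
    trace: Trace,
    chx_time_h: float,
    delay_h: float = 2.0,
    span_h: float = 12.0,
    k_seed: float = 3.0,
) -> HalfLifeFit:
    """Protein half-life from the luminescence decay after cycloheximide.

    The ``span_h`` hours of trace starting ``delay_h`` after CHX
    application are min-max normalized to [0, 1] and fit with
    ``y = e^(-t/k)`` (t re-zeroed at the segment start, k initialized at
    ``k_seed``) by nonlinear least squares.  Half-life is ``k * ln 2``.
    """
    start = chx_time_h + delay_h
    end = start + span_h
    dt = trace.dt_h
    if trace.time_h[0] > start + dt / 2 or trace.time_h[-1] < end - dt / 2:
        raise ValueError(
            f"trace [{trace.time_h[0]:.1f}, {trace.time_h[-1]:.1f}] h does not "
            f"cover the fit segment [{start:.1f}, {end:.1f}] h"
        )
    # half-sample tolerance so nominal boundaries on the sampling grid are
    # included despite floating-point drift in the time axis
    seg = trace.window(start - dt / 4, end + dt / 4)
    if seg.duration_h < span_h - dt:
        raise ValueError("segment shorter than the requested span")
    lo, hi = float(seg.value.min()), float(seg.value.max())
    if hi == lo:
        raise ValueError("constant segment: no decay to fit")
    y = (seg.value - lo) / (hi - lo)
    t = seg.time_h - seg.time_h[0]

    model = lambda tt, k: np.exp(-tt / k)
    try:
        popt, _ = curve_fit(model, t, y, p0=[k_seed], maxfev=10000)
    except RuntimeError as err:
        resid = float(np.linalg.norm(y - model(t, k_seed)))
        raise RuntimeError(
            f"decay fit did not converge (residual at seed: {resid:.3g})"
        ) from err
    k = float(popt[0])
    if k <= 0:
        raise RuntimeError(f"fit produced non-positive mean lifetime k={k:.3g}")
    resid = float(np.linalg.norm(y - model(t, k)))
    return HalfLifeFit(
        k_h=k,
        half_life_h=k * float(np.log(2.0)),
        residual_norm=resid,
        window=(start, span_h),
        slice_id=trace.slice_id,
    )
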