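"""Binned-pixel microscopy pipeline: denoising, masking, binning, phase coherence.

The chain for a CCD recording of a tissue slice: trim to a fixed frame
count, remove single-frame CCD artifacts with a 2-frame pixelwise
minimum, (optionally) mask the tissue on a whole-recording mean
projection, sum-bin pixels 4x4, extract the whole-slice frame-mean trace
whose peaks define cycles, call each binned pixel's peaks with the same
sliding-slope detector used for whole traces, express pixel peak times
relative to the per-cycle mean, and summarize phase coherence per cycle
by the raw median absolute deviation (MAD, no consistency constant).
Group dispersion trajectories are compared with an extra-sum-of-squares
F test for unshared slope of MAD against cycle number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage.draw import polygon2mask

from .core import AnalysisConfig, ImageStack, Trace
from .preprocess import detrend, rolling_mean
from .waveform import CyclePeaks, find_peaks_troughs

__all__ = [
    "trim_frames",
    "two_frame_min",
    "make_mask",
    "bin_pixels",
    "frame_mean_trace",
    "pixel_peak_table",
    "phase_dispersion",
    "PhaseDispersion",
    "SlopeComparison",
    "compare_dispersion_slopes",
]


def trim_frames(stack: ImageStack, n: int = 190) -> ImageStack:
    """Keep the first ``n`` frames; shorter stacks pass through with a warning."""
    if n < 2:
        raise ValueError("need at least 2 frames after trimming")
    if stack.n_frames < n:
        warnings.warn(
            f"stack has {stack.n_frames} frames, fewer than trim target {n}; "
            "passing through unchanged",
            stacklevel=2,
        )
        return stack
    return ImageStack(
        stack.intensity[:n].copy(), stack.frame_interval_h,
        None if stack.mask is None else stack.mask.copy(), dict(stack.meta),
    )


def two_frame_min(stack: ImageStack) -> ImageStack:
    """Pixelwise minimum of consecutive frame pairs.

    Removes artifacts present in exactly one frame (CCD hot pixels /
    cosmic hits); the output has one frame fewer and is pointwise <= the
    input.
    """
    out = np.minimum(stack.intensity[:-1], stack.intensity[1:])
    return ImageStack(
        out, stack.frame_interval_h,
        None if stack.mask is None else stack.mask.copy(), dict(stack.meta),
    )


def make_mask(
    stack: ImageStack,
    roi_polygon: Optional[np.ndarray] = None,
    threshold: Optional[float] = None,
) -> np.ndarray:
    """Binary tissue mask from the whole-recording mean projection.

    ``roi_polygon`` ((row, col) vertices) emulates a manual outline;
    otherwise ``threshold`` keeps projection pixels at or above that
    intensity.  Exactly one of the two must be given.
    """
    if (roi_polygon is None) == (threshold is None):
        raise ValueError("give exactly one of roi_polygon or threshold")
    projection = stack.intensity.mean(axis=0)
    if roi_polygon is not None:
        mask = polygon2mask(projection.shape, np.asarray(roi_polygon, dtype=float))
    else:
        mask = projection >= threshold
    if not mask.any():
        raise ValueError("mask is empty")
    return mask


def bin_pixels(
    stack: ImageStack,
    factor: int = 4,
    mask: Optional[np.ndarray] = None,
    min_coverage: float = 0.5,
) -> tuple[ImageStack, np.ndarray]:
    """Sum-bin frames into non-overlapping ``factor`` x ``factor`` blocks.

    Partial edge blocks are dropped.  Returns the binned stack and a
    boolean keep-map: a binned pixel is retained only when at least
    ``min_coverage`` of its source pixels are in-mask (all retained when
    no mask).  Binning by sum preserves photon statistics; downstream
    phase measures are scale-invariant either way.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    n, h, w = stack.intensity.shape
    hb, wb = h // factor, w // factor
    if hb < 1 or wb < 1:
        raise ValueError(f"bin factor {factor} larger than frame {h}x{w}")
    clipped = stack.intensity[:, : hb * factor, : wb * factor]
    binned = clipped.reshape(n, hb, factor, wb, factor).sum(axis=(2, 4))
    if mask is None:
        mask = stack.mask
    if mask is None:
        keep = np.ones((hb, wb), dtype=bool)
    else:
        mclip = np.asarray(mask, bool)[: hb * factor, : wb * factor]
        cov = mclip.reshape(hb, factor, wb, factor).mean(axis=(1, 3))
        keep = cov >= min_coverage
    out = ImageStack(binned, stack.frame_interval_h, None, dict(stack.meta))
    return out, keep


def frame_mean_trace(stack: ImageStack, mask: Optional[np.ndarray] = None) -> Trace:
    """Whole-slice longitudinal trace: mean (in-mask) intensity per frame."""
    if mask is None:
        mask = stack.mask
    if mask is None:
        value = stack.intensity.mean(axis=(1, 2))
    else:
        mask = np.asarray(mask, bool)
        if not mask.any():
            raise ValueError("mask is empty")
        value = stack.intensity[:, mask].mean(axis=1)
    return Trace(stack.time_h, value, kind="raw", meta=dict(stack.meta))


def _preprocess_pixel(trace: Trace, config: AnalysisConfig) -> Trace:
    d = detrend(trace, config.detrend_window_h)
    return rolling_mean(d, config.smooth_window_h)


def pixel_peak_table(
    binned_stack: ImageStack,
    whole_slice_peaks: CyclePeaks,
    keep: Optional[np.ndarray] = None,
    config: Optional[AnalysisConfig] = None,
) -> pd.DataFrame:
    """Per-binned-pixel, per-cycle peak times relative to the cycle mean.

    Each retained binned pixel's trace is detrended and smoothed with the
    same settings as the whole-slice trace, its peaks found with the
    sliding-slope detector (minimum spacing half the minimum scan period
    guards against noise doublets), and each pixel peak assigned to the
    whole-slice cycle with the nearest peak time (ties to the earlier
    cycle; at most one pixel peak per pixel per cycle, nearest wins).
    ``rel_peak_time_h`` is the peak time minus the mean peak time of all
    pixels in that cycle, so its per-cycle mean is zero by construction.

    Returns a tidy frame: pixel_id, bin_row, bin_col, cycle_index,
    peak_time_h, rel_peak_time_h.  Pixels with no detectable peaks
    contribute no rows; coverage is recorded in ``df.attrs['n_pixels']``
    and ``df.attrs['n_pixels_with_peaks']``.
    """
    if config is None:
        config = AnalysisConfig()
    if len(whole_slice_peaks) == 0:
        raise ValueError("whole-slice trace has no peaks to define cycles")
    n, hb, wb = binned_stack.intensity.shape
    if keep is None:
        keep = np.ones((hb, wb), dtype=bool)
    cycle_times = whole_slice_peaks.peak_time_h
    cycle_ids = whole_slice_peaks.cycle_index
    min_spacing = config.period_scan_min_h / 2.0

    rows = []
    n_pixels = int(keep.sum())
    n_with_peaks = 0
    t = binned_stack.time_h
    for r, c in np.argwhere(keep):
        trace = Trace(t, binned_stack.intensity[:, r, c], kind="raw")
        try:
            smoothed = _preprocess_pixel(trace, config)
            pk = find_peaks_troughs(
                smoothed, config.peak_fit_window_h, min_spacing_h=min_spacing
            )
        except ValueError:
            continue
        if len(pk) == 0:
            continue
        n_with_peaks += 1
        # nearest whole-slice cycle per pixel peak; one peak per cycle
        best: dict[int, tuple[float, float]] = {}
        for pt in pk.peak_time_h:
            dist = np.abs(cycle_times - pt)
            j = int(np.argmin(dist))  # argmin takes the earlier cycle on ties
            d = float(dist[j])
            cyc = int(cycle_ids[j])
            if cyc not in best or d < best[cyc][0]:
                best[cyc] = (d, float(pt))
        for cyc, (_, pt) in sorted(best.items()):
            rows.append(
                {"pixel_id": int(r * wb + c), "bin_row": int(r), "bin_col": int(c),
                 "cycle_index": cyc, "peak_time_h": pt}
            )

    df = pd.DataFrame(
        rows,
        columns=["pixel_id", "bin_row", "bin_col", "cycle_index", "peak_time_h"],
    )
    if len(df):
        df["rel_peak_time_h"] = df["peak_time_h"] - df.groupby("cycle_index")[
            "peak_time_h"
        ].transform("mean")
    else:
        df["rel_peak_time_h"] = pd.Series(dtype=float)
    df.attrs["n_pixels"] = n_pixels
    df.attrs["n_pixels_with_peaks"] = n_with_peaks
    return df


def _raw_mad(x: np.ndarray) -> float:
    """Median absolute deviation, no consistency constant."""
    x = np.asarray(x, dtype=float)
    return float(np.median(np.abs(x - np.median(x))))


@dataclass
class PhaseDispersion:
    """Per-cycle phase-coherence summary of one slice."""

    cycle_index: np.ndarray
    mad_h: np.ndarray
    n_pixels: np.ndarray
    slice_id: str = ""

    @property
    def mad_change_h(self) -> np.ndarray:
        """MAD_c - MAD_1 (dispersion change relative to the first cycle)."""
        return self.mad_h - self.mad_h[0]

    @property
    def cycle_mean_mad_h(self) -> float:
        """Mean of the per-cycle MADs (the per-slice summary)."""
        return float(np.mean(self.mad_h))


def phase_dispersion(
    table: pd.DataFrame, cycles: Optional[Sequence[int]] = None
) -> PhaseDispersion:
    """Per-cycle MAD of relative pixel peak times.

    ``cycles`` restricts to the given cycle indices (e.g. the first
    four); cycles with fewer than 2 pixels are skipped with a warning.
    """
    if cycles is None:
        cycles = sorted(table["cycle_index"].unique())
    idx, mads, counts = [], [], []
    for cyc in cycles:
        rel = table.loc[table["cycle_index"] == cyc, "rel_peak_time_h"].to_numpy()
        if len(rel) < 2:
            warnings.warn(f"cycle {cyc}: fewer than 2 pixels, skipped", stacklevel=2)
            continue
        idx.append(int(cyc))
        mads.append(_raw_mad(rel))
        counts.append(len(rel))
    if not idx:
        raise ValueError("no cycle has at least 2 pixels")
    return PhaseDispersion(
        cycle_index=np.array(idx), mad_h=np.array(mads), n_pixels=np.array(counts)
    )


@dataclass
class SlopeComparison:
    """Extra-sum-of-squares F test for unshared slope of MAD vs cycle."""

    slopes: dict            # group -> fitted slope (full model), h/cycle
    intercepts: dict        # group -> fitted intercept (full model), h
    rss_shared: float
    rss_separate: float
    f_stat: float
    df_num: int
    df_den: int
    p_value: float


def compare_dispersion_slopes(
    group_a: pd.DataFrame, group_b: pd.DataFrame
) -> SlopeComparison:
    """Do two groups' dispersion trajectories have different slopes?

    Inputs are tidy frames with columns ``cycle_index`` and ``mad_h``
    (one row per slice per cycle; a ``slice_id`` column is allowed and
    ignored).  The reduced model fits a common slope with per-group
    intercepts; the full model fits per-group slopes and intercepts.
    F = ((RSS_red - RSS_full) / d_extra) / (RSS_full / df_full).
    """
    frames = []
    for name, df in (("A", group_a), ("B", group_b)):
        if len(df) < 3:
            raise ValueError(f"group {name} has fewer than 3 points")
        frames.append(
            pd.DataFrame(
                {"x": df["cycle_index"].to_numpy(float),
                 "y": df["mad_h"].to_numpy(float),
                 "g": name}
            )
        )
    data = pd.concat(frames, ignore_index=True)
    x = data["x"].to_numpy()
    y = data["y"].to_numpy()
    is_b = (data["g"] == "B").to_numpy(float)

    def rss(design):
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        r = y - design @ beta
        return float(r @ r), beta

    ones = np.ones_like(x)
    rss_full, beta_full = rss(np.column_stack([ones, is_b, x, is_b * x]))
    rss_red, _ = rss(np.column_stack([ones, is_b, x]))

    df_den = len(y) - 4
    if df_den < 1:
        raise ValueError("too few points for the separate-slopes model")
    rss_red = max(rss_red, rss_full)  # guard tiny negative rounding
    f = ((rss_red - rss_full) / 1.0) / (rss_full / df_den)
    p = float(stats.f.sf(f, 1, df_den))
    return SlopeComparison(
        slopes={"A": float(beta_full[2]), "B": float(beta_full[2] + beta_full[3])},
        intercepts={"A": float(beta_full[0]), "B": float(beta_full[0] + beta_full[1])},
        rss_shared=rss_red,
        rss_separate=rss_full,
        f_stat=float(f),
        df_num=1,
        df_den=df_den,
        p_value=p,
    )
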