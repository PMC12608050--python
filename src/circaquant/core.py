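"""Core containers for circadian trace and image-stack analysis.

Time is always hours from recording start; circadian-time (CT/ZT) labels
belong in metadata, never in the time axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

__all__ = [
    "Trace",
    "ImageStack",
    "AnalysisConfig",
    "TraceKind",
]

#: allowed values of :attr:`Trace.kind`
TraceKind = ("raw", "detrended", "smoothed", "normalized")


@dataclass
class Trace:
    """A uniformly sampled signal time series from one slice/recording.

    Parameters
    ----------
    time_h : array of float
        Sample times in hours, strictly increasing, nominally uniform
        (1/6 h for luminometer exports, 1 h for PER2::LUC imaging,
        1/3 h for GCaMP imaging).
    value : array of float
        Signal in instrument units (photon counts, fluorescence a.u.).
    kind : str
        One of ``raw``, ``detrended``, ``smoothed``, ``normalized``.
    meta : dict
        Free-form provenance: ``slice_id``, group label, tissue, treatment,
        and an ``interpolated`` boolean array marking points replaced by
        the aberrant-count filter.
    """

    time_h: np.ndarray
    value: np.ndarray
    kind: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time_h.ndim != 1 or self.value.ndim != 1:
            raise ValueError("time_h and value must be 1-D")
        if len(self.time_h) != len(self.value):
            raise ValueError(
                f"length mismatch: {len(self.time_h)} times, {len(self.value)} values"
            )
        if len(self.time_h) >= 2 and not np.all(np.diff(self.time_h) > 0):
            raise ValueError("time_h must be strictly increasing")
        if not np.all(np.isfinite(self.time_h)):
            raise ValueError("non-finite sample times")
        if not np.all(np.isfinite(self.value)):
            raise ValueError("non-finite signal values")
        if self.kind not in TraceKind:
            raise ValueError(f"kind must be one of {TraceKind}, got {self.kind!r}")

    def __len__(self) -> int:
        return len(self.time_h)

    @property
    def dt_h(self) -> float:
        """Median sampling interval in hours."""
        if len(self) < 2:
            raise ValueError("need at least 2 samples to define dt")
        return float(np.median(np.diff(self.time_h)))

    @property
    def duration_h(self) -> float:
        return float(self.time_h[-1] - self.time_h[0])

    @property
    def slice_id(self) -> str:
        return str(self.meta.get("slice_id", ""))

    def replace(self, value=None, kind=None, **meta_updates) -> "Trace":
        """Return a copy with new values and/or kind, preserving the time axis."""
        new_meta = dict(self.meta)
        new_meta.update(meta_updates)
        return Trace(
            time_h=self.time_h.copy(),
            value=self.value.copy() if value is None else np.asarray(value, float),
            kind=self.kind if kind is None else kind,
            meta=new_meta,
        )

    def window(self, start_h: float, end_h: float) -> "Trace":
        """Sub-trace with start_h <= t <= end_h (closed interval)."""
        sel = (self.time_h >= start_h) & (self.time_h <= end_h)
        if not sel.any():
            raise ValueError(f"window [{start_h}, {end_h}] h contains no samples")
        out = Trace(self.time_h[sel], self.value[sel], self.kind, dict(self.meta))
        if "interpolated" in out.meta and np.ndim(out.meta["interpolated"]) == 1:
            out.meta["interpolated"] = np.asarray(self.meta["interpolated"])[sel]
        return out


@dataclass
class ImageStack:
    """A frames x rows x cols stack of nonnegative intensities.

    ``frame_interval_h`` converts frame index to hours; an optional binary
    ``mask`` marks in-tissue pixels (liver recordings are typically
    analyzed unmasked, SCN recordings masked).
    """

    intensity: np.ndarray
    frame_interval_h: float
    mask: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be frames x rows x cols")
        if self.intensity.shape[0] < 2:
            raise ValueError("stack needs at least 2 frames")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities")
        if not (np.isfinite(self.frame_interval_h) and self.frame_interval_h > 0):
            raise ValueError("frame_interval_h must be positive and finite")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.intensity.shape[1:]:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match frame shape "
                    f"{self.intensity.shape[1:]}"
                )

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[0]

    @property
    def frame_shape(self) -> tuple:
        return self.intensity.shape[1:]

    @property
    def time_h(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_h


@dataclass
class AnalysisConfig:
    """Pipeline parameters.

    Analysis windows are configuration, not constants: published analyses
    of the same pipeline use 72-168 h, 24-144 h, 120-240 h and 0-240 h
    windows depending on the experiment.
    """

    period_window_start_h: float = 72.0
    period_window_end_h: float = 168.0
    period_scan_min_h: float = 16.0
    period_scan_max_h: float = 32.0
    filter_window_h: float = 2.0
    filter_k: float = 8.0
    detrend_window_h: float = 24.0
    smooth_window_h: float = 2.0
    peak_fit_window_h: float = 8.0
    alpha: float = 0.01
    halflife_delay_h: float = 2.0
    halflife_span_h: float = 12.0
    bin_factor: int = 4
    trim_frames: int = 190
    oversample: int = 10

    def __post_init__(self):
        for name in (
            "filter_window_h", "detrend_window_h", "smooth_window_h",
            "peak_fit_window_h", "halflife_span_h",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.period_window_start_h >= self.period_window_end_h:
            raise ValueError("period window start must precede end")
        if self.period_scan_min_h >= self.period_scan_max_h:
            raise ValueError("period scan min must be below max")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        return cls(**d)
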