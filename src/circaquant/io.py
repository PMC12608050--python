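"""Reading and writing traces, image stacks, and configuration.

Traces travel as CSV in two documented dialects — long
(``slice_id,time_h,signal``) and wide (a ``time_h`` column plus one
column per slice).  Instrument-native exports (LumiCycle, uManager) are a
pre-conversion concern.  Stacks are standard multi-page grayscale TIFF
with the frame interval and metadata in a ``<stem>.yaml`` sidecar.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import AnalysisConfig, ImageStack, Trace

__all__ = [
    "read_traces",
    "write_traces",
    "read_stack",
    "write_stack",
    "read_config",
    "write_config",
]


def read_traces(path, dialect: str = "long_csv") -> list[Trace]:
    """Read one Trace per slice from a CSV file.

    ``long_csv`` expects columns slice_id, time_h, signal; ``wide_csv``
    a time_h column plus one signal column per slice.  Times are sorted;
    duplicated (slice, time) pairs are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    traces = []
    if dialect == "long_csv":
        required = {"slice_id", "time_h", "signal"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"{path}: long CSV needs columns {sorted(required)}, "
                f"found {list(df.columns)}"
            )
        for slice_id, sub in df.groupby("slice_id", sort=True):
            sub = sub.sort_values("time_h")
            if sub["time_h"].duplicated().any():
                raise ValueError(f"{path}: duplicate timestamps for slice {slice_id!r}")
            traces.append(
                Trace(
                    sub["time_h"].to_numpy(float),
                    sub["signal"].to_numpy(float),
                    kind="raw",
                    meta={"slice_id": str(slice_id), "source": str(path)},
                )
            )
    elif dialect == "wide_csv":
        if "time_h" not in df.columns:
            raise ValueError(f"{path}: wide CSV needs a time_h column")
        if df["time_h"].duplicated().any():
            raise ValueError(f"{path}: duplicate timestamps in time_h")
        df = df.sort_values("time_h")
        t = df["time_h"].to_numpy(float)
        for col in df.columns:
            if col == "time_h":
                continue
            traces.append(
                Trace(
                    t.copy(), df[col].to_numpy(float), kind="raw",
                    meta={"slice_id": str(col), "source": str(path)},
                )
            )
    else:
        raise ValueError("dialect must be 'long_csv' or 'wide_csv'")
    return traces


def write_traces(traces: list[Trace], path) -> None:
    """Write traces as long-format CSV (slice_id, time_h, signal)."""
    frames = [
        pd.DataFrame(
            {"slice_id": tr.meta.get("slice_id", f"trace{i}"),
             "time_h": tr.time_h, "signal": tr.value}
        )
        for i, tr in enumerate(traces)
    ]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["slice_id", "time_h", "signal"]
    )
    out.to_csv(path, index=False)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as multi-page grayscale TIFF plus a YAML sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.intensity.astype(np.float32), photometric="minisblack")
    sidecar = {
        "frame_interval_h": float(stack.frame_interval_h),
        "meta": {k: v for k, v in stack.meta.items() if np.isscalar(v) or isinstance(v, str)},
    }
    if stack.mask is not None:
        sidecar["mask"] = stack.mask.astype(int).tolist()
    _sidecar(path).write_text(yaml.safe_dump(sidecar))


def read_stack(path, frame_interval_h: Optional[float] = None) -> ImageStack:
    """Read a multi-page single-channel TIFF stack.

    The frame interval comes from the YAML sidecar written alongside, or
    from the ``frame_interval_h`` argument.  RGB / multi-channel input,
    stacks with fewer than 2 frames, and mixed page dtypes are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        dtypes = {page.dtype for page in tif.pages}
        if len(dtypes) > 1:
            raise ValueError(f"{path}: mixed page dtypes {sorted(map(str, dtypes))}")
        if any(page.samplesperpixel > 1 for page in tif.pages):
            raise ValueError(f"{path}: RGB/multi-sample input, need single channel")
        arr = tif.asarray()
    if arr.ndim == 2:
        raise ValueError(f"{path}: single-frame TIFF, need at least 2 frames")
    if arr.ndim != 3:
        raise ValueError(
            f"{path}: expected a single-channel frames x rows x cols stack, "
            f"got shape {arr.shape} (RGB or multi-channel input?)"
        )

    mask = None
    meta: dict = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        info = yaml.safe_load(sidecar.read_text()) or {}
        meta = info.get("meta", {}) or {}
        if frame_interval_h is None:
            frame_interval_h = info.get("frame_interval_h")
        if "mask" in info:
            mask = np.asarray(info["mask"], dtype=bool)
    if frame_interval_h is None:
        raise ValueError(
            f"{path}: frame interval unknown; no sidecar and no frame_interval_h given"
        )
    meta.setdefault("source", str(path))
    return ImageStack(arr.astype(float), float(frame_interval_h), mask, meta)


def read_config(path) -> AnalysisConfig:
    """Load an AnalysisConfig from YAML (missing keys take defaults)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return AnalysisConfig.from_dict(data)


def write_config(config: AnalysisConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict()))
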