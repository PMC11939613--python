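"""Circular-ROI intensity extraction and trace-table I/O.

Mirrors the manual imaging workflow: a circular region is drawn over each
cell body in a time-lapse stack, and the mean pixel intensity of that region
in every frame forms the cell's fluorescence time series.  Pixel membership
is center-in-disk (a pixel belongs to the ROI iff its integer center lies
within the Euclidean radius), which makes extraction integer-exact and
reproducible across platforms; no anti-aliased partial pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Roi",
    "Trace",
    "disk_mask",
    "extract_roi_trace",
    "extract_all",
    "sample_cells",
    "read_stack",
    "write_stack",
    "read_roi_csv",
    "write_roi_csv",
    "read_trace_table",
    "write_trace_table",
]


@dataclass(frozen=True)
class Roi:
    """A circular cell-body selection, in 0-based pixel coordinates."""

    roi_id: str
    center_x: float
    center_y: float
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"ROI {self.roi_id!r}: radius must be > 0, got {self.radius}")

    def is_inside(self, frame_shape: tuple[int, int]) -> bool:
        """True iff the full disk lies within a (rows, cols) frame."""
        nrows, ncols = frame_shape
        return (
            self.center_x - self.radius >= -0.5
            and self.center_x + self.radius <= ncols - 0.5
            and self.center_y - self.radius >= -0.5
            and self.center_y + self.radius <= nrows - 0.5
        )


@dataclass
class Trace:
    """One cell's fluorescence time series (arbitrary units)."""

    cell_id: str
    fps: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError(f"trace {self.cell_id!r}: need >=2 samples, got shape {self.values.shape}")
        if not self.fps > 0:
            raise ValueError(f"trace {self.cell_id!r}: fps must be > 0, got {self.fps}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"trace {self.cell_id!r}: non-finite sample values")

    @property
    def n_frames(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


def disk_mask(frame_shape: tuple[int, int], roi: Roi) -> np.ndarray:
    """Boolean mask of pixels whose centers lie within the ROI disk."""
    nrows, ncols = frame_shape
    yy, xx = np.mgrid[0:nrows, 0:ncols]
    return (xx - roi.center_x) ** 2 + (yy - roi.center_y) ** 2 <= roi.radius**2


def extract_roi_trace(stack: np.ndarray, roi: Roi, fps: float) -> Trace:
    """Mean intensity of the ROI disk in every frame of a (T, H, W) stack."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError(f"stack must be a non-empty (frames, rows, cols) array, got shape {stack.shape}")
    if not roi.is_inside(stack.shape[1:]):
        raise ValueError(f"ROI {roi.roi_id!r} extends outside the {stack.shape[1:]} frame")
    mask = disk_mask(stack.shape[1:], roi)
    if not mask.any():
        raise ValueError(f"ROI {roi.roi_id!r} covers no pixel centers")
    values = stack[:, mask].mean(axis=1)
    return Trace(cell_id=roi.roi_id, fps=fps, values=values)


def extract_all(stack: np.ndarray, rois: Sequence[Roi], fps: float) -> list[Trace]:
    return [extract_roi_trace(stack, roi, fps) for roi in rois]


def sample_cells(
    rois: Sequence[Roi],
    k: int,
    seed: int,
    frame_shape: tuple[int, int] | None = None,
) -> list[Roi]:
    """Uniform sample of ``k`` ROIs without replacement, deterministic under ``seed``.

    Border-clipped ROIs (disks not fully inside ``frame_shape``) are excluded
    from eligibility when a frame shape is given, since partial cells bias
    the ROI mean.
    """
    if frame_shape is not None:
        eligible = [r for r in rois if r.is_inside(frame_shape)]
    else:
        eligible = list(rois)
    if k > len(eligible):
        raise ValueError(f"requested k={k} cells but only {len(eligible)} eligible ROIs")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=k, replace=False)
    return [eligible[i] for i in sorted(idx)]


# ---------------------------------------------------------------------------
# File I/O


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page grayscale TIFF as a (frames, rows, cols) float array."""
    arr = np.asarray(tifffile.imread(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a grayscale multi-page TIFF, got shape {arr.shape}")
    return arr.astype(float)


def write_stack(frames: np.ndarray, path: str | Path, dtype: str = "uint16") -> None:
    """Write a (frames, rows, cols) array as a multi-page TIFF.

    ``dtype='uint16'`` rounds and clips to the 16-bit range (the standard
    camera format); ``dtype='float32'`` preserves values exactly.
    """
    frames = np.asarray(frames)
    if dtype == "uint16":
        out = np.clip(np.round(frames), 0, 65535).astype(np.uint16)
    elif dtype == "float32":
        out = frames.astype(np.float32)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
    tifffile.imwrite(path, out)


def write_roi_csv(rois: Sequence[Roi], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "roi_id": [r.roi_id for r in rois],
            "center_x": [r.center_x for r in rois],
            "center_y": [r.center_y for r in rois],
            "radius_px": [r.radius for r in rois],
        }
    )
    df.to_csv(path, index=False)


def read_roi_csv(path: str | Path) -> list[Roi]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"roi_id", "center_x", "center_y", "radius_px"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing ROI columns {sorted(missing)}")
    return [
        Roi(roi_id=str(row.roi_id), center_x=float(row.center_x), center_y=float(row.center_y), radius=float(row.radius_px))
        for row in df.itertuples()
    ]


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def write_trace_table(traces: Sequence[Trace], path: str | Path) -> None:
    """Write traces as a TSV/CSV table: ``time_s`` column plus one column per cell.

    All traces must share fps and frame count. Column headers are the cell
    identifiers (``well:cell`` for cohort recordings).
    """
    if not traces:
        raise ValueError("no traces to write")
    fps = traces[0].fps
    n = traces[0].n_frames
    for t in traces:
        if t.fps != fps or t.n_frames != n:
            raise ValueError(f"trace {t.cell_id!r} has fps={t.fps}, n={t.n_frames}; expected fps={fps}, n={n}")
    ids = [t.cell_id for t in traces]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate cell identifiers in trace table")
    data = {"time_s": np.arange(n) / fps}
    for t in traces:
        data[t.cell_id] = t.values
    pd.DataFrame(data).to_csv(path, index=False, sep=_sep_for(path))


def read_trace_table(path: str | Path, fps: float | None = None) -> list[Trace]:
    """Read a trace table, inferring fps from the ``time_s`` column step.

    A supplied ``fps`` that disagrees with the time column is an error (no
    silent resampling). Non-finite samples, ragged/missing values and a
    non-monotonic time axis are parse errors naming the offending column.
    """
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: first column must be 'time_s'")
    time = df["time_s"].to_numpy(dtype=float)
    if time.size < 2:
        raise ValueError(f"{path}: need >=2 rows")
    steps = np.diff(time)
    if np.any(steps <= 0):
        bad = int(np.argmax(steps <= 0)) + 1
        raise ValueError(f"{path}: non-monotonic time at row {bad}")
    step = float(np.median(steps))
    if not np.allclose(steps, step, rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: non-uniform time steps; cannot infer fps")
    inferred = 1.0 / step
    if abs(inferred - round(inferred)) < 1e-6 * inferred:
        inferred = float(round(inferred))
    if fps is not None and not np.isclose(fps, inferred, rtol=1e-6):
        raise ValueError(f"{path}: supplied fps={fps} disagrees with time column (step implies {inferred:g})")
    traces = []
    for col in df.columns:
        if col == "time_s":
            continue
        vals = df[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            bad = int(np.argmax(~np.isfinite(vals)))
            raise ValueError(f"{path}: cell {col!r} has a missing/non-finite sample at row {bad}")
        traces.append(Trace(cell_id=str(col), fps=inferred, values=vals))
    if not traces:
        raise ValueError(f"{path}: no cell columns")
    return traces
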