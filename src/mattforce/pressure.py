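"""Pressure-mat recordings: reading, windowing, averaging, unit conversion, heatmaps.

The sensor mat is a 24x48 grid (24 cells across the mattress width, 48 along
its length) with a cell pitch of 36.25 mm. Raw recordings are time series of
24x48 scalar matrices in mmHg or Newtons; downstream force computation wants a
single time-averaged grid in Newtons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

GRID_SHAPE = (24, 48)
CELL_PITCH_MM = 36.25
#: Pa per mmHg; with the full cell area this converts sensor mmHg to Newtons.
MMHG_TO_PA = 133.322


class PressureShapeError(ValueError):
    """A frame does not have the 24x48 sensor layout."""


class PressureValidationError(ValueError):
    """Negative values, bad timestamps, or unit misuse."""


@dataclass(frozen=True)
class PressureRecording:
    """A time series of pressure-mat frames.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, 24, 48)
        Non-negative sensor readings; axis 1 indexes the mat width (x),
        axis 2 the mat length (y).
    timestamps : ndarray, shape (n_frames,)
        Strictly increasing acquisition times in seconds.
    units : {"mmHg", "N"}
    """

    frames: np.ndarray
    timestamps: np.ndarray
    units: str = "mmHg"

    def __post_init__(self):
        frames = np.asarray(self.frames, dtype=float)
        ts = np.asarray(self.timestamps, dtype=float)
        if frames.ndim != 3 or frames.shape[1:] != GRID_SHAPE:
            raise PressureShapeError(
                f"expected frames of shape (n, 24, 48), got {frames.shape}"
            )
        if frames.shape[0] != ts.shape[0]:
            raise PressureValidationError("frame/timestamp count mismatch")
        if np.any(frames < 0):
            raise PressureValidationError("negative pressure values")
        if ts.size > 1 and not np.all(np.diff(ts) > 0):
            raise PressureValidationError("timestamps must be strictly increasing")
        if self.units not in ("mmHg", "N"):
            raise PressureValidationError(f"unknown units {self.units!r}")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "timestamps", ts)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        if self.n_frames == 0:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass(frozen=True)
class PressureGrid:
    """A single (typically time-averaged) 24x48 pressure grid.

    ``origin_convention`` records which corner cell (0, 0) sits at; the
    lower-left convention matches the mat's documented coordinate frame and
    is what region indexing assumes.
    """

    values: np.ndarray
    units: str = "N"
    cell_pitch_mm: float = CELL_PITCH_MM
    frame: str = "mat"
    origin_convention: str = "lower_left"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != GRID_SHAPE:
            raise PressureShapeError(f"expected 24x48 grid, got {values.shape}")
        if np.any(values < 0):
            raise PressureValidationError("negative pressure values")
        if self.cell_pitch_mm <= 0:
            raise PressureValidationError("cell pitch must be positive")
        if self.origin_convention not in ("lower_left", "centroid"):
            raise PressureValidationError(
                f"unknown origin convention {self.origin_convention!r}"
            )
        object.__setattr__(self, "values", values)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-center coordinates (x, y) in mm, each shaped (24, 48).

        x runs along the mat width (first index), y along the length
        (second index), measured from the grid's lower-left corner.
        """
        p = self.cell_pitch_mm
        x = (np.arange(GRID_SHAPE[0]) + 0.5) * p
        y = (np.arange(GRID_SHAPE[1]) + 0.5) * p
        return np.meshgrid(x, y, indexing="ij")

    def total(self) -> float:
        """Sum of all cell values (total force when units are N)."""
        return float(self.values.sum())


# ---------------------------------------------------------------------------
# I/O

def _parse_frame_block(lines: Sequence[str], lineno: int) -> np.ndarray:
    rows = []
    for i, line in enumerate(lines):
        parts = [p for p in line.replace("\t", ",").split(",") if p.strip() != ""]
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise PressureValidationError(
                f"line {lineno + i}: non-numeric value"
            ) from exc
    arr = np.asarray(rows, dtype=float)
    if arr.shape != GRID_SHAPE:
        raise PressureShapeError(
            f"frame starting at line {lineno} has shape {arr.shape}, expected 24x48"
        )
    return arr


def read_pressure_recording(path: str | Path, units: str = "mmHg") -> PressureRecording:
    """Read a multi-frame recording from CSV/TSV or JSON.

    CSV layout: each frame is a ``# t=<seconds>`` header line followed by
    24 lines of 48 comma- (or tab-) separated values. JSON layout:
    ``{"timestamps": [...], "frames": [[[...]]]}``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if path.suffix.lower() == ".json" or text.lstrip().startswith("{"):
        payload = json.loads(text)
        return PressureRecording(
            np.asarray(payload["frames"], dtype=float),
            np.asarray(payload["timestamps"], dtype=float),
            units=payload.get("units", units),
        )
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    frames, timestamps = [], []
    i = 0
    while i < len(lines):
        header = lines[i].strip()
        if not header.startswith("#"):
            raise PressureValidationError(
                f"line {i}: expected '# t=<seconds>' frame header, got {header!r}"
            )
        try:
            timestamps.append(float(header.lstrip("#").strip().removeprefix("t=")))
        except ValueError as exc:
            raise PressureValidationError(f"line {i}: bad timestamp header") from exc
        block = lines[i + 1 : i + 1 + GRID_SHAPE[0]]
        if len(block) < GRID_SHAPE[0]:
            raise PressureShapeError("truncated final frame")
        frames.append(_parse_frame_block(block, i + 1))
        i += 1 + GRID_SHAPE[0]
    return PressureRecording(np.asarray(frames), np.asarray(timestamps), units=units)


def write_pressure_recording(rec: PressureRecording, path: str | Path) -> None:
    """Write a recording in the CSV frame-block format (lossless via repr floats)."""
    path = Path(path)
    with path.open("w") as fh:
        for t, frame in zip(rec.timestamps, rec.frames):
            fh.write(f"# t={float(t)!r}\n")
            for row in frame:
                fh.write(",".join(repr(float(v)) for v in row) + "\n")


def read_pressure_grid(path: str | Path, units: str = "N") -> PressureGrid:
    """Read a single pre-averaged 24x48 grid from a plain CSV matrix."""
    arr = np.loadtxt(Path(path), delimiter=",", dtype=float)
    return PressureGrid(arr, units=units)


def write_pressure_grid(grid: PressureGrid, path: str | Path) -> None:
    np.savetxt(Path(path), grid.values, delimiter=",", fmt="%.17g")


# ---------------------------------------------------------------------------
# Processing

def select_middle_window(rec: PressureRecording, window_s: float) -> PressureRecording:
    """Keep the frames in the central ``window_s`` seconds of the recording.

    The window is centered on the timestamp midpoint and closed on both
    ends: frames with t in [t_mid - w/2, t_mid + w/2] survive. Selecting the
    middle 10 s of a 30 s recording discards the settling-in and rising-out
    transients at either end.
    """
    if rec.n_frames == 0 or rec.duration < window_s:
        raise ValueError(
            f"window of {window_s} s exceeds recording duration {rec.duration} s"
        )
    t_mid = 0.5 * (rec.timestamps[0] + rec.timestamps[-1])
    lo, hi = t_mid - window_s / 2.0, t_mid + window_s / 2.0
    keep = (rec.timestamps >= lo) & (rec.timestamps <= hi)
    return PressureRecording(rec.frames[keep], rec.timestamps[keep], units=rec.units)


def average_frames(rec: PressureRecording) -> PressureGrid:
    """Per-cell arithmetic mean over all frames; units carried through."""
    if rec.n_frames == 0:
        raise ValueError("cannot average an empty recording")
    return PressureGrid(rec.frames.mean(axis=0), units=rec.units)


def convert_to_newtons(
    grid: PressureGrid, mmhg_to_pa: float = MMHG_TO_PA
) -> PressureGrid:
    """Convert an mmHg grid to per-cell force in Newtons.

    F[N] = P[mmHg] * 133.322 Pa/mmHg * (0.03625 m)^2, i.e. the sensor
    pressure applied uniformly over the full cell area. Calibrated devices
    can override ``mmhg_to_pa``.
    """
    if grid.units != "mmHg":
        raise PressureValidationError(f"grid already in {grid.units}, expected mmHg")
    area_m2 = (grid.cell_pitch_mm / 1000.0) ** 2
    return replace(grid, values=grid.values * mmhg_to_pa * area_m2, units="N")


def to_heatmap(grid: PressureGrid, path: str | Path, cmap: str = "rocket_r") -> Path:
    """Render the grid as a PNG heatmap with cell (0, 0) at the lower-left.

    The mat length (48 cells) runs horizontally, width (24 cells) vertically,
    matching the orientation of a body lying along the mat.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    fig, ax = plt.subplots(figsize=(10, 5))
    # flip rows so cell (0, 0) renders at the lower-left corner
    sns.heatmap(
        grid.values[::-1],
        ax=ax,
        cmap=cmap,
        cbar_kws={"label": f"pressure ({grid.units})"},
        xticklabels=8,
        yticklabels=4,
    )
    ax.set_xlabel("length cell index (y)")
    ax.set_ylabel("width cell index (x)")
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
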