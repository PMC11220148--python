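"""Per-cell vector forces: bin scan points into sensor cells, average their
normals, and scale each cell's scalar pressure force along its unit normal.

This is the heart of the method: a pressure mat only measures the scalar
force magnitude per 36.25 mm cell, but the deformed mattress surface tells
us the direction of support. The per-cell force vector is

    F_s = F * n_s

where F is the cell's scalar force (N) and n_s the unit mean normal of the
registered scan points falling inside that cell. Its vertical component is
the cell's contribution to supporting body weight; the horizontal components
are the shear the mattress exerts on the body.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .cloud import SurfaceCloud
from .pressure import GRID_SHAPE, PressureGrid


class FrameMismatchError(ValueError):
    """Cloud and grid are not expressed in the same coordinate frame."""


class DegenerateCellError(ValueError):
    """Per-point normals cancel; the mean has no direction."""


class CoverageError(ValueError):
    """A loaded cell has no scan points under the strict empty-cell policy."""


@dataclass(frozen=True)
class CellBinning:
    """Scan points grouped by sensor cell.

    ``counts[i, j]`` is the number of points binned into cell (i, j);
    ``indices`` maps each cell to the point indices it received;
    ``n_discarded`` counts points outside the grid footprint.
    """

    counts: np.ndarray
    indices: dict[tuple[int, int], np.ndarray]
    n_discarded: int


@dataclass(frozen=True)
class CellNormalField:
    """Per-cell mean unit normals with point counts.

    Cells with ``counts == 0`` have no defined normal; ``unit_normals`` holds
    NaN there and ``occupied`` flags where a normal exists.
    """

    counts: np.ndarray
    unit_normals: np.ndarray  # (24, 48, 3), NaN where unoccupied

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0


@dataclass(frozen=True)
class VectorForceField:
    """Per-cell force vectors (N) with cell-center positions (mm)."""

    forces: np.ndarray        # (24, 48, 3)
    positions: np.ndarray     # (24, 48, 2) cell centers, mat frame, mm
    scalar_forces: np.ndarray  # (24, 48) N
    point_counts: np.ndarray   # (24, 48)

    def component_sums(self) -> tuple[float, float, float]:
        s = self.forces.reshape(-1, 3).sum(axis=0)
        return float(s[0]), float(s[1]), float(s[2])

    def to_dataframe(self):
        import pandas as pd

        ii, jj = np.meshgrid(
            np.arange(GRID_SHAPE[0]), np.arange(GRID_SHAPE[1]), indexing="ij"
        )
        return pd.DataFrame(
            {
                "row": ii.ravel(),
                "col": jj.ravel(),
                "x_mm": self.positions[..., 0].ravel(),
                "y_mm": self.positions[..., 1].ravel(),
                "F_N": self.scalar_forces.ravel(),
                "fx_N": self.forces[..., 0].ravel(),
                "fy_N": self.forces[..., 1].ravel(),
                "fz_N": self.forces[..., 2].ravel(),
                "n_points": self.point_counts.ravel(),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(Path(path), index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "VectorForceField":
        import pandas as pd

        df = pd.read_csv(Path(path))
        forces = np.zeros(GRID_SHAPE + (3,))
        positions = np.zeros(GRID_SHAPE + (2,))
        scalar = np.zeros(GRID_SHAPE)
        counts = np.zeros(GRID_SHAPE, dtype=int)
        r, c = df["row"].to_numpy(), df["col"].to_numpy()
        forces[r, c, 0] = df["fx_N"]
        forces[r, c, 1] = df["fy_N"]
        forces[r, c, 2] = df["fz_N"]
        positions[r, c, 0] = df["x_mm"]
        positions[r, c, 1] = df["y_mm"]
        scalar[r, c] = df["F_N"]
        counts[r, c] = df["n_points"]
        return cls(forces, positions, scalar, counts)


def bin_points_to_cells(
    cloud: SurfaceCloud, grid: PressureGrid, require_frame: bool = True
) -> CellBinning:
    """Assign each scan point to the sensor cell whose footprint contains it.

    Cells are half-open boxes [i*p, (i+1)*p) x [j*p, (j+1)*p) in the grid's
    lower-left-origin frame, so every point lands in exactly one cell; points
    outside the 24x48 footprint are discarded (and counted).
    """
    if require_frame and cloud.frame != grid.frame:
        raise FrameMismatchError(
            f"cloud frame {cloud.frame!r} != grid frame {grid.frame!r}"
        )
    p = grid.cell_pitch_mm
    ij = np.floor(cloud.points[:, :2] / p).astype(int)
    inside = (
        (ij[:, 0] >= 0)
        & (ij[:, 0] < GRID_SHAPE[0])
        & (ij[:, 1] >= 0)
        & (ij[:, 1] < GRID_SHAPE[1])
    )
    counts = np.zeros(GRID_SHAPE, dtype=int)
    kept = np.flatnonzero(inside)
    np.add.at(counts, (ij[kept, 0], ij[kept, 1]), 1)
    indices: dict[tuple[int, int], np.ndarray] = {}
    if kept.size:
        flat = ij[kept, 0] * GRID_SHAPE[1] + ij[kept, 1]
        order = np.argsort(flat, kind="stable")
        sorted_flat = flat[order]
        starts = np.flatnonzero(np.r_[True, np.diff(sorted_flat) > 0])
        bounds = np.r_[starts, sorted_flat.size]
        for s, e in zip(bounds[:-1], bounds[1:]):
            cell = int(sorted_flat[s])
            indices[(cell // GRID_SHAPE[1], cell % GRID_SHAPE[1])] = kept[order[s:e]]
    return CellBinning(counts, indices, int((~inside).sum()))


def cell_mean_unit_normal(normals: np.ndarray) -> np.ndarray:
    """Componentwise mean of per-point unit normals, renormalized to length 1.

    Raises :class:`DegenerateCellError` when the normals cancel (mean norm
    below 1e-9) — that indicates a registration failure, not a usable cell.
    """
    normals = np.asarray(normals, dtype=float).reshape(-1, 3)
    if normals.shape[0] == 0:
        raise ValueError("cell has no points")
    mean = normals.mean(axis=0)
    norm = np.linalg.norm(mean)
    if norm < 1e-9:
        raise DegenerateCellError("mean normal has near-zero norm")
    return mean / norm


def compute_cell_normals(
    cloud: SurfaceCloud, grid: PressureGrid, binning: CellBinning | None = None
) -> CellNormalField:
    """Mean unit normal per occupied sensor cell (requires per-point normals)."""
    if not cloud.has_normals:
        raise ValueError("cloud has no normals; run estimate_normals first")
    if binning is None:
        binning = bin_points_to_cells(cloud, grid)
    unit = np.full(GRID_SHAPE + (3,), np.nan)
    for (i, j), idx in binning.indices.items():
        unit[i, j] = cell_mean_unit_normal(cloud.normals[idx])
    return CellNormalField(binning.counts, unit)


def compute_vector_force(F: float, n_s: np.ndarray) -> np.ndarray:
    """Scale the scalar cell force along the cell's unit normal: F_s = F n_s."""
    n_s = np.asarray(n_s, dtype=float).reshape(3)
    if F < 0:
        raise ValueError("scalar force must be non-negative")
    if abs(np.linalg.norm(n_s) - 1.0) > 1e-6:
        raise ValueError("normal must be unit length")
    return F * n_s


def compute_force_field(
    grid: PressureGrid,
    normals: CellNormalField,
    cloud: SurfaceCloud | None = None,
    policy: str = "nearest",
) -> VectorForceField:
    """Assemble the full per-cell vector force field.

    Cells with pressure but no scan points (scan shadows) are handled per
    ``policy``:

    - ``"nearest"`` (default): borrow the mean unit normal of the nearest
      k=8 scan points to the cell center, falling back to vertical (0,0,1)
      when none lie within two cell pitches — requires ``cloud``;
    - ``"vertical"``: use (0, 0, 1);
    - ``"strict"``: raise :class:`CoverageError`.
    """
    if policy not in ("nearest", "vertical", "strict"):
        raise ValueError(f"unknown empty-cell policy {policy!r}")
    xc, yc = grid.cell_centers()
    forces = np.zeros(GRID_SHAPE + (3,))
    loaded = grid.values > 0
    missing = loaded & ~normals.occupied
    if policy == "strict" and np.any(missing):
        n_bad = int(missing.sum())
        raise CoverageError(f"{n_bad} loaded cells have no scan points")
    filled = np.where(
        normals.occupied[..., None], np.nan_to_num(normals.unit_normals), 0.0
    )
    if np.any(missing):
        if policy == "vertical" or cloud is None or not cloud.has_normals:
            filled[missing] = np.array([0.0, 0.0, 1.0])
        else:
            tree = cKDTree(cloud.points[:, :2])
            centers = np.column_stack([xc[missing], yc[missing]])
            k = min(8, len(cloud))
            d, idx = tree.query(centers, k=k)
            d = np.atleast_2d(d)
            idx = np.atleast_2d(idx)
            borrowed = np.zeros((centers.shape[0], 3))
            for m in range(centers.shape[0]):
                near = idx[m][d[m] <= 2 * grid.cell_pitch_mm]
                if near.size == 0:
                    borrowed[m] = (0.0, 0.0, 1.0)
                else:
                    borrowed[m] = cell_mean_unit_normal(cloud.normals[near])
            filled[missing] = borrowed
    forces[loaded] = grid.values[loaded, None] * filled[loaded]
    positions = np.stack([xc, yc], axis=-1)
    return VectorForceField(forces, positions, grid.values.copy(), normals.counts)
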