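"""Reduce the distributed force field to one wrench per body region.

Musculoskeletal models take contact loads as a small set of boundary
conditions, not 1152 cell forces. Each body region (head, chest, waist,
hips, legs) is an inclusive rectangle of sensor cells; its distributed load
reduces to a resultant force F_A = sum F_i, a resultant couple about the mat
origin M_A = sum r_i x F_i, and an application point r_A in the sensor
plane — the generalization of the center of pressure.

Solving r_A from (F_A, M_A) requires care: the matrix form of "r x F = M"
is a cross-product matrix, which is singular (rank 2) for every F, so it
cannot be inverted literally. The physically meaningful resolution for a
planar contact is implemented instead: M_A is split into its component
parallel to F_A (the "free" or residual moment, which no pure force
placement can reproduce) and the perpendicular remainder, and
r_A x F_A = M_perp is solved with r_A constrained to the sensor plane
z = 0 (minimum-norm in the plane when underdetermined).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .forcefield import VectorForceField
from .pressure import GRID_SHAPE


class SingularWrenchError(ValueError):
    """Resultant force too small to define an application point."""


class RegionConfigError(ValueError):
    """Overlapping or out-of-bounds region definitions."""


@dataclass(frozen=True)
class RegionSpec:
    """An inclusive rectangle of sensor cells in the lower-left-origin frame."""

    label: str
    x_b: int
    y_b: int
    x_e: int
    y_e: int

    def __post_init__(self):
        if not (0 <= self.x_b <= self.x_e < GRID_SHAPE[0]):
            raise RegionConfigError(
                f"{self.label}: x range [{self.x_b}, {self.x_e}] outside grid"
            )
        if not (0 <= self.y_b <= self.y_e < GRID_SHAPE[1]):
            raise RegionConfigError(
                f"{self.label}: y range [{self.y_b}, {self.y_e}] outside grid"
            )

    def mask(self) -> np.ndarray:
        m = np.zeros(GRID_SHAPE, dtype=bool)
        m[self.x_b : self.x_e + 1, self.y_b : self.y_e + 1] = True
        return m


@dataclass(frozen=True)
class RegionalWrench:
    """Equivalent wrench of one region's distributed load.

    ``F_A`` in N; ``M_A`` (about the mat origin) and ``residual_moment`` in
    N*mm; ``r_A`` in mm with z = 0. ``residual_moment`` is the signed
    magnitude of M_A's component along F_A.
    """

    label: str
    F_A: np.ndarray
    M_A: np.ndarray
    r_A: np.ndarray
    residual_moment: float

    def reconstruct_moment(self) -> np.ndarray:
        """r_A x F_A + residual * F_hat; equals M_A for a valid solve."""
        f_hat = self.F_A / np.linalg.norm(self.F_A)
        return np.cross(self.r_A, self.F_A) + self.residual_moment * f_hat


def cell_moment(r: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Moment of one cell force about the origin: M = r x F (N*mm)."""
    return np.cross(np.asarray(r, dtype=float), np.asarray(F, dtype=float))


def cross_matrix(F: np.ndarray) -> np.ndarray:
    """Skew-symmetric matrix [F]x with [F]x v = F x v. Always rank 2."""
    fx, fy, fz = np.asarray(F, dtype=float).reshape(3)
    return np.array([[0.0, -fz, fy], [fz, 0.0, -fx], [-fy, fx, 0.0]])


def region_resultant(
    fld: VectorForceField, spec: RegionSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Resultant force and moment (about the mat origin) of a region.

    Returns (F_A [N], M_A [N*mm]); a region with no loaded cells yields the
    zero wrench (callers should warn).
    """
    m = spec.mask()
    forces = fld.forces[m]
    pos = np.concatenate(
        [fld.positions[m], np.zeros((int(m.sum()), 1))], axis=1
    )
    F_A = forces.sum(axis=0)
    M_A = np.cross(pos, forces).sum(axis=0)
    return F_A, M_A


def solve_application_point(
    F_A: np.ndarray, M_A: np.ndarray, tol: float = 1e-9
) -> tuple[np.ndarray, float]:
    """Application point in the sensor plane plus the residual (free) moment.

    Decomposes M_A into components parallel and perpendicular to F_A, then
    solves r x F_A = M_perp for r = (x, y, 0) by least squares (minimum-norm
    within the plane when rank-deficient). Returns (r_A, residual) where
    residual is the signed magnitude of the parallel component.
    """
    F_A = np.asarray(F_A, dtype=float).reshape(3)
    M_A = np.asarray(M_A, dtype=float).reshape(3)
    norm_f = np.linalg.norm(F_A)
    if norm_f <= tol:
        raise SingularWrenchError("resultant force is (near) zero")
    f_hat = F_A / norm_f
    residual = float(M_A @ f_hat)
    m_perp = M_A - residual * f_hat
    # r x F for planar r spans {e_x x F, e_y x F}
    A = np.column_stack([np.cross([1.0, 0.0, 0.0], F_A), np.cross([0.0, 1.0, 0.0], F_A)])
    xy, *_ = np.linalg.lstsq(A, m_perp, rcond=None)
    r_A = np.array([xy[0], xy[1], 0.0])
    return r_A, residual


def reduce_regions(
    fld: VectorForceField, specs: list[RegionSpec], min_force: float = 1e-9
) -> list[RegionalWrench]:
    """One wrench per region; zero-load regions produce a zero wrench."""
    _check_overlap(specs)
    out = []
    for spec in specs:
        F_A, M_A = region_resultant(fld, spec)
        if np.linalg.norm(F_A) <= min_force:
            out.append(
                RegionalWrench(spec.label, F_A, M_A, np.zeros(3), 0.0)
            )
            continue
        r_A, residual = solve_application_point(F_A, M_A)
        out.append(RegionalWrench(spec.label, F_A, M_A, r_A, residual))
    return out


def _check_overlap(specs: list[RegionSpec]) -> None:
    acc = np.zeros(GRID_SHAPE, dtype=int)
    for s in specs:
        acc += s.mask()
    if np.any(acc > 1):
        raise RegionConfigError("region definitions overlap")


# ---------------------------------------------------------------------------
# Region layout I/O and defaults

def load_region_layout(path: str | Path) -> list[RegionSpec]:
    """Read a YAML/JSON list of {label, x_b, y_b, x_e, y_e}."""
    text = Path(path).read_text()
    payload = yaml.safe_load(text)
    specs = [RegionSpec(**entry) for entry in payload]
    _check_overlap(specs)
    return specs


def default_region_layout(posture: str) -> list[RegionSpec]:
    """Editable default head/chest/waist/hips/legs bands along the mat length.

    These are starting points for a roughly centered adult body, meant to be
    adjusted against the pressure heatmap for each subject — they are not
    anatomical truth.
    """
    if posture not in ("supine", "lateral"):
        raise ValueError(f"unknown posture {posture!r}")
    bands = [("legs", 0, 17), ("hips", 18, 24), ("waist", 25, 30),
             ("chest", 31, 39), ("head", 40, 47)]
    return [RegionSpec(label, 0, y0, GRID_SHAPE[0] - 1, y1) for label, y0, y1 in bands]


def export_boundary_conditions(
    wrenches: list[RegionalWrench], posture: str, path: str | Path
) -> Path:
    """Write per-region wrenches as SI boundary conditions (N, N*m, m).

    Internal mm quantities are converted to metres; the file header states
    the units and the moment origin so downstream models cannot misread
    them.
    """
    if not wrenches:
        raise ValueError("no wrenches to export")
    payload = {
        "units": {"force": "N", "moment": "N*m", "position": "m"},
        "moment_origin": "pressure-mat lower-left corner, sensor plane z=0",
        "posture": posture,
        "regions": [
            {
                "label": w.label,
                "F_A": w.F_A.tolist(),
                "M_A": (w.M_A / 1000.0).tolist(),
                "r_A": (w.r_A / 1000.0).tolist(),
                "residual_moment": w.residual_moment / 1000.0,
            }
            for w in wrenches
        ],
    }
    path = Path(path)
    existing = {}
    if path.exists():
        try:
            existing = json.loads(path.read_text())
        except (json.JSONDecodeError, OSError):
            existing = {}
    if "postures" in existing:
        existing["postures"][posture] = payload
        path.write_text(json.dumps(existing, indent=2))
    else:
        path.write_text(json.dumps({"postures": {posture: payload}}, indent=2))
    return path


def import_boundary_conditions(path: str | Path) -> dict[str, list[RegionalWrench]]:
    """Read boundary conditions back (m, N*m) into mm-native wrenches."""
    payload = json.loads(Path(path).read_text())
    out: dict[str, list[RegionalWrench]] = {}
    for posture, block in payload["postures"].items():
        out[posture] = [
            RegionalWrench(
                label=r["label"],
                F_A=np.asarray(r["F_A"]),
                M_A=np.asarray(r["M_A"]) * 1000.0,
                r_A=np.asarray(r["r_A"]) * 1000.0,
                residual_moment=r["residual_moment"] * 1000.0,
            )
            for r in block["regions"]
        ]
    return out
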