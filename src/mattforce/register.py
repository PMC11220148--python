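"""Rigid registration of the pressure cloud onto the scanned mattress surface.

The pressure-mat cloud (source) and the vacuum-mattress scan (target) start
in different frames. A deterministic coarse alignment (centroid translation
plus in-plane principal-axis rotation) replaces the manual nudging a human
operator would do, and point-to-point ICP refines it. All transforms are
strictly rigid: p' = R p + t with R in SO(3).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .cloud import SurfaceCloud

#: default correspondence radius: two sensor-cell pitches
DEFAULT_MAX_CORR_DIST_MM = 72.5


class ConvergenceError(RuntimeError):
    """ICP could not establish correspondences at the initial transform."""


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion: rotation (3x3, det +1) plus translation (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation must have determinant +1 (no reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def __eq__(self, other):
        if not isinstance(other, RigidTransform):
            return NotImplemented
        return np.array_equal(self.rotation, other.rotation) and np.array_equal(
            self.translation, other.translation
        )

    __hash__ = None

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec_deg(cls, rotvec_deg, translation) -> "RigidTransform":
        from scipy.spatial.transform import Rotation

        R = Rotation.from_rotvec(np.asarray(rotvec_deg, float), degrees=True)
        return cls(R.as_matrix(), translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self @ other)(p) = self(other(p))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    def rotation_angle_deg(self) -> float:
        from scipy.spatial.transform import Rotation

        return float(
            np.degrees(np.linalg.norm(Rotation.from_matrix(self.rotation).as_rotvec()))
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "rotation": self.rotation.tolist(),
                    "translation": self.translation.tolist(),
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RigidTransform":
        payload = json.loads(Path(path).read_text())
        return cls(np.asarray(payload["rotation"]), np.asarray(payload["translation"]))


@dataclass(frozen=True)
class RegistrationResult:
    transform: RigidTransform
    rmse: float
    inlier_fraction: float
    iterations: int
    rmse_trace: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")
        if not 0.0 <= self.inlier_fraction <= 1.0:
            raise ValueError("inlier fraction must lie in [0, 1]")


def apply_transform(cloud: SurfaceCloud, t: RigidTransform) -> SurfaceCloud:
    """Transform points; normals are rotated only (directions do not translate)."""
    pts = t.apply(cloud.points)
    normals = None if cloud.normals is None else cloud.normals @ t.rotation.T
    return replace(cloud, points=pts, normals=normals)


def _principal_axis_2d(points: np.ndarray) -> np.ndarray:
    """Unit direction of largest x-y spread."""
    xy = points[:, :2] - points[:, :2].mean(axis=0)
    cov = xy.T @ xy
    w, v = np.linalg.eigh(cov)
    return v[:, -1]


def _nn_rmse(source: np.ndarray, tree: cKDTree) -> float:
    d, _ = tree.query(source)
    return float(np.sqrt(np.mean(d**2)))


def coarse_align(
    source: SurfaceCloud,
    target: SurfaceCloud,
    init: RigidTransform | None = None,
) -> RigidTransform:
    """Deterministic initial alignment of source onto target.

    If ``init`` is given it is returned unchanged (operator-supplied
    initialization wins). Otherwise the clouds' centroids are matched and the
    source is rotated about z so its in-plane principal axis aligns with the
    target's. The two sign ambiguities (axis direction x in-plane flip) are
    resolved by evaluating nearest-neighbor RMSE for all four candidate
    rotations and keeping the best.
    """
    if init is not None:
        return init
    if len(source) == 0 or len(target) == 0:
        raise ValueError("cannot align empty clouds")
    cs, ct = source.points.mean(axis=0), target.points.mean(axis=0)
    a_s, a_t = _principal_axis_2d(source.points), _principal_axis_2d(target.points)
    tree = cKDTree(target.points)
    best: tuple[float, RigidTransform] | None = None
    for sign in (1.0, -1.0):
        axis = sign * a_s
        ang = np.arctan2(a_t[1], a_t[0]) - np.arctan2(axis[1], axis[0])
        for extra in (0.0, np.pi):
            c, s = np.cos(ang + extra), np.sin(ang + extra)
            R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
            t = ct - R @ cs
            cand = RigidTransform(R, t)
            rmse = _nn_rmse(cand.apply(source.points), tree)
            if best is None or rmse < best[0]:
                best = (rmse, cand)
    return best[1]


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping src onto dst (SVD, no reflection)."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, cd - R @ cs)


def icp_refine(
    source: SurfaceCloud,
    target: SurfaceCloud,
    t0: RigidTransform | None = None,
    max_corr_dist: float = DEFAULT_MAX_CORR_DIST_MM,
    max_iter: int = 200,
    tol: float = 1e-6,
    abs_tol: float = 1e-9,
) -> RegistrationResult:
    """Point-to-point ICP refinement of an initial rigid transform.

    Correspondences are nearest target neighbors within ``max_corr_dist``
    mm of each transformed source point; each iteration re-estimates the
    rigid transform by SVD over the inlier pairs. Stops when the inlier RMSE
    changes by less than ``tol`` (relative) or after ``max_iter`` rounds.
    """
    if len(source) == 0 or len(target) == 0:
        raise ValueError("cannot register empty clouds")
    if max_corr_dist <= 0:
        raise ValueError("max_corr_dist must be positive")
    t = t0 if t0 is not None else RigidTransform.identity()
    tree = cKDTree(target.points)
    trace: list[float] = []
    prev_rmse = np.inf
    n_inl = 0
    for it in range(1, max_iter + 1):
        moved = t.apply(source.points)
        d, idx = tree.query(moved, distance_upper_bound=max_corr_dist)
        inliers = np.isfinite(d)
        n_inl = int(inliers.sum())
        if n_inl < 3:
            raise ConvergenceError(
                f"only {n_inl} correspondences within {max_corr_dist} mm at "
                f"iteration {it}; increase max_corr_dist or improve the "
                "initial alignment"
            )
        rmse = float(np.sqrt(np.mean(d[inliers] ** 2)))
        trace.append(rmse)
        if rmse <= abs_tol or abs(prev_rmse - rmse) <= tol * max(rmse, 1e-30):
            break
        prev_rmse = rmse
        step = _kabsch(moved[inliers], target.points[idx[inliers]])
        t = step.compose(t)
    return RegistrationResult(
        transform=t,
        rmse=trace[-1],
        inlier_fraction=n_inl / len(source),
        iterations=len(trace),
        rmse_trace=tuple(trace),
    )


def register(
    source: SurfaceCloud,
    target: SurfaceCloud,
    init: RigidTransform | None = None,
    max_corr_dist: float = DEFAULT_MAX_CORR_DIST_MM,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> RegistrationResult:
    """Coarse alignment followed by ICP refinement (the standard pipeline)."""
    t0 = coarse_align(source, target, init=init)
    return icp_refine(
        source, target, t0, max_corr_dist=max_corr_dist, max_iter=max_iter, tol=tol
    )


def correlation_refine(
    grid,
    target: SurfaceCloud,
    t0: RigidTransform,
    max_shift_mm: float = 15.0,
    max_rot_rad: float = 0.03,
    max_iter: int = 600,
) -> RigidTransform:
    """Amplitude-robust in-plane refinement of a pressure-to-scan transform.

    ICP matches the pressure cloud's surrogate z profile against the real
    indentation depths, so any mismatch between pressure amplitude and
    depth amplitude (pressure is not strictly proportional to indentation)
    biases the in-plane alignment by up to a couple of sensor cells. This
    stage corrects that by maximizing the Pearson correlation between the
    scalar pressure image and the indentation depth sampled under each cell
    center: for indentation lobes that are individually symmetric, the
    correlation peaks at the true in-plane pose regardless of per-lobe
    amplitude disagreement.

    Optimizes an in-plane shift plus rotation about the loaded-area centroid
    with Nelder-Mead (initial steps ``max_shift_mm`` / ``max_rot_rad``) and
    returns the corrected mat-to-scan transform.
    """
    from scipy import optimize

    mat_pts = t0.inverse().apply(target.points)
    tree = cKDTree(mat_pts[:, :2])
    zs = mat_pts[:, 2]
    xc, yc = grid.cell_centers()
    mask = grid.values > 0
    if mask.sum() < 4:
        return t0
    F = grid.values[mask]
    cx, cy = float(xc[mask].mean()), float(yc[mask].mean())
    rel = np.column_stack([xc[mask] - cx, yc[mask] - cy])

    def neg_corr(p):
        dx, dy, th = p
        c, s = np.cos(th), np.sin(th)
        xy = rel @ np.array([[c, s], [-s, c]]) + [cx + dx, cy + dy]
        d, idx = tree.query(xy, k=4)
        w = 1.0 / np.maximum(d, 1e-6)
        depth = -(w * zs[idx]).sum(axis=1) / w.sum(axis=1)
        return -np.corrcoef(F, depth)[0, 1]

    sim = np.array(
        [
            [0.0, 0.0, 0.0],
            [max_shift_mm, 0.0, 0.0],
            [0.0, max_shift_mm, 0.0],
            [0.0, 0.0, max_rot_rad],
        ]
    )
    res = optimize.minimize(
        neg_corr,
        np.zeros(3),
        method="Nelder-Mead",
        options=dict(initial_simplex=sim, xatol=1e-2, fatol=1e-12, maxiter=max_iter),
    )
    dx, dy, th = res.x
    c, s = np.cos(th), np.sin(th)
    Rc = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    tcorr = np.array([cx + dx, cy + dy, 0.0]) - Rc @ np.array([cx, cy, 0.0])
    return t0.compose(RigidTransform(Rc, tcorr))
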