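"""Synthetic scenarios with exact ground truth for every pipeline stage.

A scenario is a sum of Gaussian indentation lobes on the mattress surface —
chosen because their depth field, gradient, and hence unit normal are all
closed-form — plus a pressure grid constructed so the per-cell vertical
force components sum exactly to a prescribed body weight, a known rigid
transform separating the mat frame from the scanner frame, and optional
Gaussian noise on points and pressures.

The presets caricature the two study postures: a supine body produces five
lobes (head, chest, waist, hips, legs) symmetric about the mat's long
mid-axis; a side-lying body produces fewer, laterally offset lobes. They
are test caricatures, not anthropometric models.

Coordinates follow the pressure grid's lower-left-origin frame: x in
[0, 870] mm across the width, y in [0, 1740] mm along the length, z up
(surface depths negative).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .cloud import SurfaceCloud
from .pressure import CELL_PITCH_MM, GRID_SHAPE, PressureGrid
from .register import RigidTransform

FOOTPRINT_MM = (GRID_SHAPE[0] * CELL_PITCH_MM, GRID_SHAPE[1] * CELL_PITCH_MM)

#: measurement-noise levels used by the stochastic test conditions:
#: scanner point noise sigma (mm) and pressure noise as a fraction of the
#: peak cell force.
STATED_POINT_NOISE_MM = 0.5
STATED_PRESSURE_NOISE_FRAC = 0.01


@dataclass(frozen=True)
class Lobe:
    """One Gaussian indentation: depth A*exp(-dx^2/2sx^2 - dy^2/2sy^2)."""

    center: tuple[float, float]
    depth: float
    widths: tuple[float, float]
    load_share: float

    def __post_init__(self):
        if self.depth <= 0 or min(self.widths) <= 0 or self.load_share < 0:
            raise ValueError("lobe depth/widths must be positive, share >= 0")


@dataclass(frozen=True)
class SyntheticScenario:
    lobes: tuple[Lobe, ...]
    body_weight: float
    true_transform: RigidTransform
    point_noise_mm: float = 0.0
    pressure_noise_n: float = 0.0
    seed: int = 0
    preset: str = ""

    def __post_init__(self):
        if self.body_weight <= 0:
            raise ValueError("body weight must be positive")
        if self.lobes and not np.isclose(
            sum(l.load_share for l in self.lobes), 1.0
        ):
            raise ValueError("lobe load shares must sum to 1")


@dataclass(frozen=True)
class GroundTruth:
    """Everything the pipeline should recover, exactly.

    ``normal_at(x, y)`` evaluates the analytic unit normal in the mat frame;
    ``true_forces`` are the per-cell force vectors (N) whose vertical
    components sum to the body weight; ``true_grid`` is the noise-free
    scalar pressure grid; ``true_transform`` maps mat-frame points into the
    scanner frame.
    """

    normal_at: Callable[[np.ndarray, np.ndarray], np.ndarray]
    depth_at: Callable[[np.ndarray, np.ndarray], np.ndarray]
    true_forces: np.ndarray
    true_grid: PressureGrid
    true_transform: RigidTransform


def _depth_and_gradient(lobes, x, y):
    """Depth g(x,y) >= 0 and its gradient; z = -g."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    g = np.zeros(np.broadcast(x, y).shape)
    gx = np.zeros_like(g)
    gy = np.zeros_like(g)
    for lb in lobes:
        cx, cy = lb.center
        sx, sy = lb.widths
        e = lb.depth * np.exp(-((x - cx) ** 2) / (2 * sx**2) - ((y - cy) ** 2) / (2 * sy**2))
        g = g + e
        gx = gx - e * (x - cx) / sx**2
        gy = gy - e * (y - cy) / sy**2
    return g, gx, gy


def _make_normal_fn(lobes):
    def normal_at(x, y):
        _, gx, gy = _depth_and_gradient(lobes, x, y)
        # z = -g so the outward (upward) normal is prop. to (-dz/dx, -dz/dy, 1)
        n = np.stack([gx, gy, np.ones_like(gx)], axis=-1)
        return n / np.linalg.norm(n, axis=-1, keepdims=True)

    return normal_at


def make_surface(
    scenario: SyntheticScenario,
    lattice_mm: float = 8.0,
    include_normals: bool = True,
) -> tuple[SurfaceCloud, Callable]:
    """Sample the indented surface on a lattice and move it to the scan frame.

    Returns the cloud (scanner frame, with the true transform applied and
    point noise added afterwards) and the analytic mat-frame unit-normal
    function. Normals stored on the cloud are the analytic ones rotated into
    the scan frame, mimicking a scanner export.
    """
    if lattice_mm <= 0:
        raise ValueError("lattice spacing must be positive")
    xs = np.arange(0.5 * lattice_mm, FOOTPRINT_MM[0], lattice_mm)
    ys = np.arange(0.5 * lattice_mm, FOOTPRINT_MM[1], lattice_mm)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    g, _, _ = _depth_and_gradient(scenario.lobes, X, Y)
    pts = np.column_stack([X.ravel(), Y.ravel(), -g.ravel()])
    normal_at = _make_normal_fn(scenario.lobes)
    normals = normal_at(X.ravel(), Y.ravel()) if include_normals else None
    t = scenario.true_transform
    pts = t.apply(pts)
    if normals is not None:
        normals = normals @ t.rotation.T
    if scenario.point_noise_mm > 0:
        rng = np.random.default_rng(scenario.seed + 1)
        pts = pts + rng.normal(0.0, scenario.point_noise_mm, pts.shape)
    cloud = SurfaceCloud(pts, normals, frame="scan")
    return cloud, normal_at


def make_pressure(
    scenario: SyntheticScenario, with_noise: bool = True
) -> tuple[PressureGrid, GroundTruth]:
    """Build the force-balanced pressure grid and full ground truth.

    Per cell, the candidate vertical load is the load-share-weighted local
    indentation depth; vertical loads are rescaled so they sum exactly to
    the body weight G, then converted to scalar cell forces F = f_z / n_z
    using the analytic normal at the cell center (a tilted cell must push
    harder than its vertical share). Pressure noise, when enabled, is added
    to the scalar forces afterwards and clipped at zero.
    """
    grid_geom = PressureGrid(np.zeros(GRID_SHAPE))
    xc, yc = grid_geom.cell_centers()
    v = np.zeros(GRID_SHAPE)
    for lb in scenario.lobes:
        cx, cy = lb.center
        sx, sy = lb.widths
        e = np.exp(-((xc - cx) ** 2) / (2 * sx**2) - ((yc - cy) ** 2) / (2 * sy**2))
        v += lb.load_share * lb.depth * e
    # drop the far tails so unloaded mat cells read zero, like a real mat
    v[v < 1e-4 * v.max()] = 0.0
    fz = scenario.body_weight * v / v.sum()
    normal_at = _make_normal_fn(scenario.lobes)
    n = normal_at(xc, yc)
    if np.any((fz > 0) & (n[..., 2] < 0.1)):
        raise ValueError("surface too steep under a loaded cell (n_z < 0.1)")
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(fz > 0, fz / n[..., 2], 0.0)
    true_forces = F[..., None] * n
    true_forces[fz == 0] = 0.0
    depth_fn = lambda x, y: _depth_and_gradient(scenario.lobes, x, y)[0]
    truth = GroundTruth(
        normal_at=normal_at,
        depth_at=depth_fn,
        true_forces=true_forces,
        true_grid=PressureGrid(F),
        true_transform=scenario.true_transform,
    )
    noisy = F
    if with_noise and scenario.pressure_noise_n > 0:
        rng = np.random.default_rng(scenario.seed + 2)
        noisy = np.clip(F + rng.normal(0.0, scenario.pressure_noise_n, F.shape), 0.0, None)
        noisy[F == 0] = 0.0  # noise does not wake unloaded sensors
    return PressureGrid(noisy), truth


_PRESETS = ("supine", "lateral")


def make_scenario(
    seed: int,
    preset: str = "supine",
    body_weight: float = 617.4,
    noise: str = "none",
) -> tuple[SyntheticScenario, GroundTruth]:
    """Deterministic scenario + ground truth for a posture preset.

    ``noise="none"`` yields the exact, noise-free study conditions;
    ``noise="stated"`` applies the stated measurement noise (point sigma
    0.5 mm, pressure sigma 1% of the peak cell force). The default body
    weight (617.4 N ~ 63 kg) matches a mid-cohort adult. Lobe centers get a
    small seeded jitter so different seeds exercise different geometry.
    """
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {_PRESETS}")
    rng = np.random.default_rng(seed)
    mid_x = FOOTPRINT_MM[0] / 2.0
    if preset == "supine":
        base = [
            # (label) center y, depth mm, widths (sx, sy), load share
            ("head", 1595.0, 25.0, (90.0, 80.0), 0.08),
            ("chest", 1270.0, 45.0, (150.0, 130.0), 0.31),
            ("waist", 1015.0, 30.0, (130.0, 90.0), 0.11),
            ("hips", 760.0, 55.0, (140.0, 120.0), 0.35),
            ("legs", 330.0, 25.0, (120.0, 180.0), 0.15),
        ]
        lobes = [
            Lobe(
                center=(mid_x + rng.uniform(-10, 10), cy + rng.uniform(-15, 15)),
                depth=depth * rng.uniform(0.9, 1.1),
                widths=widths,
                load_share=share,
            )
            for _, cy, depth, widths, share in base
        ]
    else:  # lateral: narrower, laterally offset contact
        off = 70.0
        base = [
            ("head", 1595.0, 30.0, (70.0, 70.0), 0.10),
            ("shoulder", 1280.0, 60.0, (90.0, 110.0), 0.30),
            ("hips", 780.0, 65.0, (95.0, 110.0), 0.40),
            ("legs", 340.0, 30.0, (80.0, 160.0), 0.20),
        ]
        lobes = [
            Lobe(
                center=(mid_x + off + rng.uniform(-10, 10), cy + rng.uniform(-15, 15)),
                depth=depth * rng.uniform(0.9, 1.1),
                widths=widths,
                load_share=share,
            )
            for _, cy, depth, widths, share in base
        ]
    shares = np.array([l.load_share for l in lobes])
    lobes = [replace(l, load_share=s) for l, s in zip(lobes, shares / shares.sum())]
    angle = rng.uniform(-6.0, 6.0)
    shift = np.array([rng.uniform(-50, 50), rng.uniform(-50, 50), rng.uniform(-10, 10)])
    true_t = RigidTransform.from_rotvec_deg([0.0, 0.0, angle], shift)
    if noise == "stated":
        point_sigma = STATED_POINT_NOISE_MM
    elif noise == "none":
        point_sigma = 0.0
    else:
        raise ValueError(f"unknown noise mode {noise!r}")
    scenario = SyntheticScenario(
        lobes=tuple(lobes),
        body_weight=body_weight,
        true_transform=true_t,
        point_noise_mm=point_sigma,
        pressure_noise_n=0.0,
        seed=int(seed),
        preset=preset,
    )
    # pressure noise scale depends on the noise-free peak force
    _, truth = make_pressure(scenario, with_noise=False)
    if noise == "stated":
        sigma = STATED_PRESSURE_NOISE_FRAC * truth.true_grid.values.max()
        scenario = replace(scenario, pressure_noise_n=float(sigma))
    return scenario, truth
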