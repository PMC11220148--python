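"""Surface point clouds: PLY I/O, pressure-grid expansion, normal estimation.

The mattress frame convention: origin at the mattress centroid, x along the
width, y along the length, z up. All lengths are millimetres. Normals, when
present, are unit vectors oriented out of the mattress toward the body
(z-component >= 0), so forces computed from them are the support forces
acting on the body.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .pressure import PressureGrid


class PlyFormatError(ValueError):
    """Malformed PLY file or missing x/y/z vertex properties."""


@dataclass(frozen=True)
class FrameSpec:
    name: str
    origin_convention: str
    axis_semantics: str


MAT_FRAME = FrameSpec(
    name="mat",
    origin_convention="mattress centroid",
    axis_semantics="x=width, y=length, z=height (up)",
)


@dataclass(frozen=True)
class SurfaceCloud:
    """3D points in mm with optional aligned unit normals.

    ``frame`` is a tag naming the coordinate frame; operations that require
    two clouds in the same frame check it.
    """

    points: np.ndarray
    normals: np.ndarray | None = None
    frame: str = "mat"

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(pts)):
            raise ValueError("non-finite point coordinates")
        object.__setattr__(self, "points", pts)
        if self.normals is not None:
            nrm = np.asarray(self.normals, dtype=float).reshape(-1, 3)
            if nrm.shape[0] != pts.shape[0]:
                raise ValueError("normal count does not match point count")
            norms = np.linalg.norm(nrm, axis=1)
            if nrm.size and np.any(np.abs(norms - 1.0) > 1e-6):
                raise ValueError("normals must be unit length")
            object.__setattr__(self, "normals", nrm)

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def has_normals(self) -> bool:
        return self.normals is not None


# ---------------------------------------------------------------------------
# PLY codec (ASCII and binary little-endian, vertex x/y/z + optional nx/ny/nz)

_PLY_TYPES = {
    "float": ("<f4", 4), "float32": ("<f4", 4),
    "double": ("<f8", 8), "float64": ("<f8", 8),
    "char": ("<i1", 1), "int8": ("<i1", 1),
    "uchar": ("<u1", 1), "uint8": ("<u1", 1),
    "short": ("<i2", 2), "int16": ("<i2", 2),
    "ushort": ("<u2", 2), "uint16": ("<u2", 2),
    "int": ("<i4", 4), "int32": ("<i4", 4),
    "uint": ("<u4", 4), "uint32": ("<u4", 4),
}


def read_ply(path: str | Path, frame: str = "mat") -> SurfaceCloud:
    """Read a PLY point cloud (ASCII or binary_little_endian).

    Vertex properties ``x, y, z`` are required; ``nx, ny, nz`` are picked up
    as normals when all three are present. Non-vertex elements (faces etc.)
    are ignored.
    """
    path = Path(path)
    with path.open("rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise PlyFormatError(f"{path}: not a PLY file")
        fmt = None
        elements: list[tuple[str, int, list[tuple[str, str]]]] = []
        while True:
            line = fh.readline()
            if not line:
                raise PlyFormatError(f"{path}: unterminated header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens or tokens[0] == "comment":
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                elements.append((tokens[1], int(tokens[2]), []))
            elif tokens[0] == "property":
                if not elements:
                    raise PlyFormatError(f"{path}: property before element")
                if tokens[1] == "list":
                    elements[-1][2].append(("list:" + tokens[2] + ":" + tokens[3], tokens[4]))
                else:
                    elements[-1][2].append((tokens[1], tokens[2]))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise PlyFormatError(f"{path}: unsupported format {fmt!r}")
        body = fh.read()

    vert = next((e for e in elements if e[0] == "vertex"), None)
    if vert is None:
        raise PlyFormatError(f"{path}: no vertex element")
    _, count, props = vert
    names = [name for _, name in props]
    if any(t.startswith("list:") for t, _ in props):
        raise PlyFormatError(f"{path}: list properties on vertices unsupported")
    for req in ("x", "y", "z"):
        if req not in names:
            raise PlyFormatError(f"{path}: missing vertex property {req!r}")
    if elements.index(vert) != 0 and fmt == "binary_little_endian":
        raise PlyFormatError(f"{path}: vertex element must come first in binary PLY")

    if count == 0:
        return SurfaceCloud(np.empty((0, 3)), None, frame=frame)
    if fmt == "ascii":
        text_rows = body.decode("ascii").split("\n")
        rows = [r.split() for r in text_rows if r.strip()][:count]
        if len(rows) < count:
            raise PlyFormatError(f"{path}: expected {count} vertices")
        data = np.asarray([[float(v) for v in r[: len(names)]] for r in rows])
        cols = {name: data[:, i] for i, name in enumerate(names)}
    else:
        dtype = np.dtype([(name, _PLY_TYPES[t][0]) for t, name in props])
        data = np.frombuffer(body[: dtype.itemsize * count], dtype=dtype, count=count)
        cols = {name: data[name].astype(float) for name in names}

    pts = np.column_stack([cols["x"], cols["y"], cols["z"]])
    normals = None
    if all(n in cols for n in ("nx", "ny", "nz")):
        normals = np.column_stack([cols["nx"], cols["ny"], cols["nz"]])
        norms = np.linalg.norm(normals, axis=1)
        # re-normalize float32 storage error
        safe = np.where(norms > 0, norms, 1.0)
        normals = normals / safe[:, None]
    return SurfaceCloud(pts, normals, frame=frame)


def write_ply(
    cloud: SurfaceCloud, path: str | Path, binary: bool = False
) -> None:
    """Write a point cloud as PLY with float32 vertices (+ normals if present)."""
    path = Path(path)
    n = len(cloud)
    props = ["x", "y", "z"] + (["nx", "ny", "nz"] if cloud.has_normals else [])
    header = ["ply"]
    header.append(
        "format binary_little_endian 1.0" if binary else "format ascii 1.0"
    )
    header.append(f"element vertex {n}")
    header += [f"property float {p}" for p in props]
    header.append("end_header")
    if cloud.has_normals:
        data = np.column_stack([cloud.points, cloud.normals]).astype(np.float32)
    else:
        data = cloud.points.astype(np.float32)
    with path.open("wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(data.tobytes())
        else:
            for row in data:
                fh.write((" ".join(f"{v:.9g}" for v in row) + "\n").encode("ascii"))


# ---------------------------------------------------------------------------
# Pressure-grid expansion

def expand_pressure_cloud(
    grid: PressureGrid, z_max: float, z_min: float, frame: str = "mat"
) -> SurfaceCloud:
    """Expand a pressure grid into a 3D point cloud for registration.

    Each nonzero cell contributes one point at its cell center (x, y) with
    z set to the normalized pressure F' = -(F / F_max) * (z_max - z_min),
    where z_max/z_min are the target scan's z extent. Heavier cells thus sit
    deeper, mimicking the indented mattress shape so that ICP has congruent
    geometry to work with. Zero-pressure cells are omitted: they carry no
    force and would bias the registration toward the undeformed plane.
    """
    if z_max <= z_min:
        raise ValueError("z_max must exceed z_min")
    f_max = grid.values.max()
    if f_max <= 0:
        raise ValueError("all-zero grid cannot be expanded (no F_max)")
    xc, yc = grid.cell_centers()
    mask = grid.values > 0
    z = -(grid.values[mask] / f_max) * (z_max - z_min)
    pts = np.column_stack([xc[mask], yc[mask], z])
    return SurfaceCloud(pts, frame=frame)


# ---------------------------------------------------------------------------
# Normal estimation

def estimate_normals(cloud: SurfaceCloud, k: int = 12) -> SurfaceCloud:
    """Estimate per-point unit normals by local plane fits over k neighbors.

    The normal is the least-spread principal direction of the k-neighborhood
    (smallest eigenvector of the local covariance); orientation is flipped so
    every normal has z >= 0 (out of the mattress). Eigenvalue ties are broken
    by preferring the candidate with the larger z-component.
    """
    if k < 3:
        raise ValueError("k must be at least 3")
    if len(cloud) < k + 1:
        raise ValueError(f"need at least {k + 1} points, have {len(cloud)}")
    tree = cKDTree(cloud.points)
    _, idx = tree.query(cloud.points, k=k + 1)
    neigh = cloud.points[idx]  # (n, k+1, 3)
    centered = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered)
    w, v = np.linalg.eigh(cov)  # ascending eigenvalues
    normals = v[:, :, 0]
    # degenerate neighborhoods (two smallest eigenvalues tie): prefer larger z
    tie = (w[:, 1] - w[:, 0]) <= 1e-12 * np.maximum(w[:, 2], 1e-30)
    if np.any(tie):
        alt = v[:, :, 1]
        better = np.abs(alt[:, 2]) > np.abs(normals[:, 2])
        swap = tie & better
        normals[swap] = alt[swap]
    flip = normals[:, 2] < 0
    normals[flip] *= -1.0
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return replace(cloud, normals=normals)
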