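"""Voxel-volume and surface-mesh ingest for shape-complexity analysis.

CT volumes arrive as RAW files with a JSON sidecar (dims, dtype, voxel size)
or as multi-page TIFF stacks.  Greyscale stacks are binarized with Otsu's
histogram threshold, internal cavities are filled (background voxels not
reachable from the border through 6-connected steps), and the solid is
converted to a point cloud of occupied-voxel centers with a known reference
volume.  Watertight surface meshes take the parallel route: signed volume by
the divergence theorem and uniform interior points by rejection sampling.
All clouds are finally scale-normalized to unit reference volume so the
downstream complexity metric is size-invariant.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import trimesh
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "VoxelGrid", "TriangleMesh", "PointCloud",
    "load_voxel_volume", "binarize", "fill_internal_cavities",
    "voxels_to_pointcloud", "load_mesh", "mesh_to_pointcloud", "normalize",
]

DEFAULT_N_POINTS = 100_000


@dataclass
class VoxelGrid:
    """Isotropic 3D lattice of grey or binary occupancy values."""

    values: np.ndarray          # (nx, ny, nz)
    voxel_size: float           # edge length, length units
    is_binary: bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("grid must be 3D with positive dims")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        if self.is_binary:
            u = np.unique(self.values)
            if not np.all(np.isin(u, [0, 1])):
                raise ValueError("binary grid must contain only {0, 1}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def occupied_count(self) -> int:
        if not self.is_binary:
            raise ValueError("occupancy undefined for grey grids")
        return int(self.values.sum())


@dataclass
class TriangleMesh:
    """Watertight-checked triangle surface."""

    vertices: np.ndarray        # (nv, 3)
    faces: np.ndarray           # (nf, 3) int
    watertight: bool

    @property
    def signed_volume(self) -> float:
        """Divergence-theorem volume: sum of signed origin tetrahedra."""
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


@dataclass
class PointCloud:
    """N×3 coordinates with the volume of the solid the points fill."""

    points: np.ndarray
    v_ref: float
    provenance: str = "synthetic"       # voxel | mesh | synthetic
    seed: int | None = None
    scale_applied: float = 1.0

    def __post_init__(self) -> None:
        self.points = np.ascontiguousarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be N×3")
        if self.points.shape[0] < 4:
            raise ValueError("need at least 4 points")
        if np.linalg.matrix_rank(self.points - self.points.mean(0)) < 3:
            raise ValueError("points are coplanar")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def save_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.points, delimiter=",", header="x,y,z", comments="")


# ---------------------------------------------------------------------------
# loading

_DTYPES = {"uint8": np.uint8, "float32": np.float32}


def load_voxel_volume(path: str | Path, metadata: dict | str | Path | None = None
                      ) -> VoxelGrid:
    """Load a RAW volume (little-endian, C order, z slowest) or a TIFF stack.

    RAW requires sidecar metadata ``{dims, dtype, voxel_size_mm}``, passed as
    a dict or a JSON path; by default ``<path>.json`` is used.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        if arr.ndim != 3:
            raise ValueError("TIFF stack must be 3D")
        vs = 1.0
        if isinstance(metadata, dict):
            vs = float(metadata.get("voxel_size_mm", 1.0))
        arr = np.ascontiguousarray(np.transpose(arr, (2, 1, 0)))  # z-slowest
        return _grid_from_values(arr, vs)

    if metadata is None:
        metadata = path.with_suffix(path.suffix + ".json")
    if not isinstance(metadata, dict):
        metadata = json.loads(Path(metadata).read_text())
    dims = tuple(int(d) for d in metadata["dims"])
    dtype = _DTYPES.get(metadata["dtype"])
    if dtype is None:
        raise ValueError(f"unsupported dtype {metadata['dtype']!r}")
    if "voxel_size" in metadata and np.ndim(metadata["voxel_size"]) == 1:
        vs3 = np.asarray(metadata["voxel_size"], dtype=float)
        if np.ptp(vs3) > 1e-12:
            raise ValueError("anisotropic voxels are unsupported; "
                             "resample upstream")
        vsize = float(vs3[0])
    else:
        vsize = float(metadata.get("voxel_size_mm", 1.0))
    raw = np.fromfile(path, dtype=np.dtype(dtype).newbyteorder("<"))
    expected = dims[0] * dims[1] * dims[2]
    if raw.size != expected:
        raise ValueError(
            f"file holds {raw.size} voxels but metadata implies {expected}")
    # C order with z slowest: stored as (nz, ny, nx); expose as (nx, ny, nz)
    arr = raw.reshape(dims[2], dims[1], dims[0]).transpose(2, 1, 0)
    return _grid_from_values(np.ascontiguousarray(arr), vsize)


def save_voxel_volume(grid: VoxelGrid, path: str | Path) -> None:
    """Write RAW + JSON sidecar in the layout :func:`load_voxel_volume` reads."""
    path = Path(path)
    arr = grid.values
    dtype = "uint8" if arr.dtype == np.uint8 else "float32"
    arr.astype(_DTYPES[dtype]).transpose(2, 1, 0).tofile(path)
    meta = {"dims": list(arr.shape), "dtype": dtype,
            "voxel_size_mm": grid.voxel_size}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def _grid_from_values(arr: np.ndarray, voxel_size: float) -> VoxelGrid:
    u = np.unique(arr)
    binary = u.size <= 2 and np.all(np.isin(u, [0, 1]))
    return VoxelGrid(arr.astype(np.uint8 if binary else arr.dtype),
                     voxel_size, bool(binary))


# ---------------------------------------------------------------------------
# binarize / fill

def binarize(grid: VoxelGrid) -> VoxelGrid:
    """Otsu threshold on the grey histogram; voxels above become foreground.

    Float inputs are min-max scaled onto a 256-bin histogram first.
    """
    if grid.is_binary:
        return grid
    vals = grid.values
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        raise ValueError("constant image: no threshold exists")
    t = threshold_otsu(vals.astype(np.float64).ravel(), nbins=256)
    return VoxelGrid((vals > t).astype(np.uint8), grid.voxel_size, True)


def fill_internal_cavities(grid: VoxelGrid) -> VoxelGrid:
    """Fill background not reachable from the grid border (6-connectivity)."""
    if not grid.is_binary:
        raise ValueError("fill requires a binary grid")
    filled = ndimage.binary_fill_holes(grid.values)  # default structure = 6-conn
    return VoxelGrid(filled.astype(np.uint8), grid.voxel_size, True)


# ---------------------------------------------------------------------------
# point clouds

def voxels_to_pointcloud(grid: VoxelGrid, n: int = DEFAULT_N_POINTS,
                         seed: int | None = None) -> PointCloud:
    """Uniform sample (without replacement) of occupied-voxel centers.

    The reference volume is exact: occupied count × voxel volume.
    """
    if not grid.is_binary:
        raise ValueError("binarize first")
    occ = np.argwhere(grid.values > 0)
    if occ.shape[0] < 4:
        raise ValueError("fewer than 4 occupied voxels")
    v_ref = occ.shape[0] * grid.voxel_size ** 3
    rng = np.random.default_rng(seed)
    if occ.shape[0] <= n:
        if occ.shape[0] < n:
            warnings.warn(
                f"only {occ.shape[0]} occupied voxels; using all of them",
                stacklevel=2)
        pick = occ
    else:
        idx = rng.choice(occ.shape[0], size=n, replace=False)
        pick = occ[idx]
    pts = (pick + 0.5) * grid.voxel_size
    return PointCloud(pts.astype(float), v_ref, provenance="voxel", seed=seed)


def load_mesh(path: str | Path) -> TriangleMesh:
    """Load a PLY/OBJ/STL surface, fixing orientation so volume is positive."""
    m = trimesh.load_mesh(str(path), process=True)
    if isinstance(m, trimesh.Scene):
        m = m.to_mesh()
    if m.is_watertight:
        trimesh.repair.fix_normals(m)
    return TriangleMesh(np.asarray(m.vertices, dtype=float),
                        np.asarray(m.faces, dtype=int),
                        bool(m.is_watertight))


def mesh_to_pointcloud(mesh: TriangleMesh, n: int = DEFAULT_N_POINTS,
                       seed: int | None = None) -> PointCloud:
    """Uniform interior points of a watertight mesh by rejection sampling.

    Candidates are drawn in the bounding box and kept when a ray-parity
    containment test places them inside; the reference volume is the
    divergence-theorem signed volume.
    """
    if not mesh.watertight:
        raise ValueError("mesh is not watertight")
    v_ref = abs(mesh.signed_volume)
    if v_ref <= 0 or not np.isfinite(v_ref):
        raise ValueError("degenerate mesh: zero volume")
    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    box_vol = float(np.prod(hi - lo))
    rng = np.random.default_rng(seed)
    tris = mesh.vertices[mesh.faces]
    out = np.empty((0, 3))
    while out.shape[0] < n:
        need = n - out.shape[0]
        batch = max(4096, int(need * box_vol / v_ref * 1.3))
        cand = rng.uniform(lo, hi, size=(batch, 3))
        inside = _ray_parity_contains(cand, tris)
        out = np.vstack([out, cand[inside]])
    return PointCloud(out[:n], v_ref, provenance="mesh", seed=seed)


# irrational-ish direction avoids rays grazing mesh edges/vertices
_RAY_DIR = np.array([0.285968437, 0.547029428, 0.786869262])


def _ray_parity_contains(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Point-in-mesh by ray-crossing parity (vectorized Möller–Trumbore)."""
    m = points.shape[0]
    f = tris.shape[0]
    e1 = tris[:, 1] - tris[:, 0]
    e2 = tris[:, 2] - tris[:, 0]
    pvec = np.cross(_RAY_DIR, e2)                       # (f, 3)
    det = np.einsum("fj,fj->f", e1, pvec)
    ok = np.abs(det) > 1e-14
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    crossings = np.zeros(m, dtype=np.int64)
    chunk = max(1, int(4_000_000 // max(f, 1)))
    for i0 in range(0, m, chunk):
        P = points[i0:i0 + chunk]                       # (c, 3)
        tvec = P[:, None, :] - tris[None, :, 0, :]      # (c, f, 3)
        u = np.einsum("cfj,fj->cf", tvec, pvec) * inv_det
        qvec = np.cross(tvec, e1[None, :, :])
        v = np.einsum("cfj,j->cf", qvec, _RAY_DIR) * inv_det
        t = np.einsum("cfj,fj->cf", qvec, e2) * inv_det
        hit = ok[None, :] & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 0)
        crossings[i0:i0 + chunk] = hit.sum(axis=1)
    return crossings % 2 == 1


def normalize(pc: PointCloud) -> PointCloud:
    """Center the cloud and scale to unit reference volume.

    Coordinates are multiplied by ``v_ref**(-1/3)`` after centering, so the
    solid the points fill has volume 1; complexity values computed downstream
    become dimensionless and comparable across specimens of any size.
    """
    if pc.v_ref <= 0:
        raise ValueError("reference volume must be positive")
    scale = pc.v_ref ** (-1.0 / 3.0)
    pts = (pc.points - pc.points.mean(axis=0)) * scale
    pts -= pts.mean(axis=0)     # re-center to kill rounding drift
    return PointCloud(pts, 1.0, provenance=pc.provenance, seed=pc.seed,
                      scale_applied=scale * pc.scale_applied)
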