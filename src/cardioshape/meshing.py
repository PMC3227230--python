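"""Triangle-mesh utilities: grid meshing, inside tests, voxelization.

Surfaces in this package are parametric grids (rings of circumferential
samples stacked along a longitudinal axis).  These helpers turn such grids
into watertight triangle meshes (seam wrap + apex/base fans), test point
membership by z-ray parity, and voxelize meshes onto regular grids by
casting one ray per voxel column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .shape_model import LandmarkShape

__all__ = [
    "TriangleMesh",
    "build_ring_mesh",
    "mesh_from_landmark_grid",
    "points_inside",
    "voxelize_mesh",
]


@dataclass
class TriangleMesh:
    """Indexed triangle mesh with consistent outward orientation when closed."""

    vertices: np.ndarray  # (V, 3)
    faces: np.ndarray  # (F, 3) int
    watertight: bool = False

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @property
    def euler_characteristic(self) -> int:
        m = self.as_trimesh()
        return int(m.euler_number)


def _signed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    tri = vertices[faces]
    return float(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)


def build_ring_mesh(
    rings: np.ndarray,
    closed_u: bool = True,
    apex_point: np.ndarray | None = None,
    base_point: np.ndarray | None = None,
) -> TriangleMesh:
    """Mesh a stack of rings, optionally capping the ends with pole fans.

    Parameters
    ----------
    rings : (n_rings, n_circ, 3) array, ring 0 nearest the apex.
    closed_u : wrap the circumferential seam.
    apex_point, base_point : when given, a single vertex closing the first /
        last ring with a triangle fan.

    The mesh is re-oriented so that, when watertight, face normals point
    outward (positive signed volume).
    """
    rings = np.asarray(rings, dtype=float)
    n_r, n_c, _ = rings.shape
    verts = [rings.reshape(-1, 3)]
    faces: list[tuple[int, int, int]] = []

    def vid(i, j):  # ring i, circumferential j (wrapped)
        return i * n_c + (j % n_c)

    n_j = n_c if closed_u else n_c - 1
    for i in range(n_r - 1):
        for j in range(n_j):
            a, b = vid(i, j), vid(i, j + 1)
            c, d = vid(i + 1, j), vid(i + 1, j + 1)
            faces.append((a, b, d))
            faces.append((a, d, c))

    next_id = n_r * n_c
    if apex_point is not None:
        verts.append(np.asarray(apex_point, dtype=float).reshape(1, 3))
        for j in range(n_j):
            faces.append((next_id, vid(0, j + 1), vid(0, j)))
        next_id += 1
    if base_point is not None:
        verts.append(np.asarray(base_point, dtype=float).reshape(1, 3))
        for j in range(n_j):
            faces.append((next_id, vid(n_r - 1, j), vid(n_r - 1, j + 1)))
        next_id += 1

    V = np.concatenate(verts, axis=0)
    F = np.asarray(faces, dtype=np.int64)
    # drop degenerate triangles (repeated vertices can occur at collapsed poles)
    area2 = np.linalg.norm(np.cross(V[F[:, 1]] - V[F[:, 0]], V[F[:, 2]] - V[F[:, 0]]), axis=1)
    F = F[area2 > 1e-14]

    tm = trimesh.Trimesh(V, F, process=False)
    # merge coincident vertices so seam/pole duplicates do not break closure
    tm.merge_vertices(digits_vertex=10)
    tm.remove_unreferenced_vertices()
    watertight = bool(tm.is_watertight)
    V2, F2 = np.asarray(tm.vertices), np.asarray(tm.faces)
    if watertight and _signed_volume(V2, F2) < 0:
        F2 = F2[:, ::-1]
    return TriangleMesh(V2, F2, watertight=watertight)


def mesh_from_landmark_grid(shape: LandmarkShape, close: bool = True) -> TriangleMesh:
    """Watertight mesh from a (rows x cols) landmark grid.

    Rows are longitudinal stations (row 0 nearest the apex), columns the
    circumferential samples.  Closure adds the first/last ring centroids as
    apex/base vertices.
    """
    if shape.grid_dims is None:
        raise ValueError("landmark shape has no grid_dims; cannot mesh")
    rows, cols = shape.grid_dims
    rings = shape.points.reshape(rows, cols, 3)
    apex = rings[0].mean(axis=0) if close else None
    base = rings[-1].mean(axis=0) if close else None
    return build_ring_mesh(rings, closed_u=True, apex_point=apex, base_point=base)


def _crossings(points_xy: np.ndarray, points_z: np.ndarray,
               vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Count, per query point, triangle crossings of the +z ray above it."""
    tri = vertices[faces]  # (T, 3, 3)
    counts = np.zeros(len(points_xy), dtype=np.int64)
    px, py = points_xy[:, 0], points_xy[:, 1]
    for t in tri:
        x1, y1, z1 = t[0]
        x2, y2, z2 = t[1]
        x3, y3, z3 = t[2]
        denom = (y2 - y3) * (x1 - x3) + (x3 - x2) * (y1 - y3)
        if abs(denom) < 1e-300:
            continue  # degenerate xy projection: ray parallel to the plane
        xmin, xmax = min(x1, x2, x3), max(x1, x2, x3)
        ymin, ymax = min(y1, y2, y3), max(y1, y2, y3)
        sel = np.flatnonzero((px >= xmin) & (px <= xmax) & (py >= ymin) & (py <= ymax))
        if sel.size == 0:
            continue
        qx, qy = px[sel], py[sel]
        a = ((y2 - y3) * (qx - x3) + (x3 - x2) * (qy - y3)) / denom
        b = ((y3 - y1) * (qx - x3) + (x1 - x3) * (qy - y3)) / denom
        c = 1.0 - a - b
        inside = (a >= 0) & (b >= 0) & (c >= 0)
        if not inside.any():
            continue
        idx = sel[inside]
        zc = a[inside] * z1 + b[inside] * z2 + c[inside] * z3
        above = zc > points_z[idx]
        np.add.at(counts, idx[above], 1)
    return counts


def points_inside(points: np.ndarray, mesh: TriangleMesh) -> np.ndarray:
    """Boolean inside test by z-ray crossing parity (watertight meshes)."""
    pts = np.asarray(points, dtype=float)
    counts = _crossings(pts[:, :2], pts[:, 2], mesh.vertices, mesh.faces)
    return counts % 2 == 1


def voxelize_mesh(
    mesh: TriangleMesh,
    shape: tuple[int, int, int],
    spacing: np.ndarray,
    origin: np.ndarray,
) -> np.ndarray:
    """Boolean occupancy of voxel centers inside a watertight mesh.

    One z-ray per (x, y) voxel column; crossing z values toggle the parity of
    all voxel centers above them.  Column coordinates are nudged by a tiny
    deterministic jitter so rays never graze mesh edges exactly.
    """
    nx, ny, nz = shape
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    jit = np.array([2.718281e-7, 3.141592e-7]) * spacing[:2]
    xs = origin[0] + np.arange(nx) * spacing[0] + jit[0]
    ys = origin[1] + np.arange(ny) * spacing[1] + jit[1]
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    cols_xy = np.stack([gx.reshape(-1), gy.reshape(-1)], axis=1)  # (nx*ny, 2)

    tri = mesh.vertices[mesh.faces]
    toggles = np.zeros((nx * ny, nz + 1), dtype=np.int64)
    px, py = cols_xy[:, 0], cols_xy[:, 1]
    z0 = origin[2]
    dz = spacing[2]
    for t in tri:
        x1, y1, z1 = t[0]
        x2, y2, z2 = t[1]
        x3, y3, z3 = t[2]
        denom = (y2 - y3) * (x1 - x3) + (x3 - x2) * (y1 - y3)
        if abs(denom) < 1e-300:
            continue
        xmin, xmax = min(x1, x2, x3), max(x1, x2, x3)
        ymin, ymax = min(y1, y2, y3), max(y1, y2, y3)
        sel = np.flatnonzero((px >= xmin) & (px <= xmax) & (py >= ymin) & (py <= ymax))
        if sel.size == 0:
            continue
        qx, qy = px[sel], py[sel]
        a = ((y2 - y3) * (qx - x3) + (x3 - x2) * (qy - y3)) / denom
        b = ((y3 - y1) * (qx - x3) + (x1 - x3) * (qy - y3)) / denom
        c = 1.0 - a - b
        inside = (a >= 0) & (b >= 0) & (c >= 0)
        if not inside.any():
            continue
        idx = sel[inside]
        zc = a[inside] * z1 + b[inside] * z2 + c[inside] * z3
        # first voxel center strictly above the crossing
        iz = np.ceil((zc - z0) / dz - 1e-12).astype(np.int64)
        iz = np.clip(iz, 0, nz)
        np.add.at(toggles, (idx, iz), 1)
    parity = np.cumsum(toggles[:, :nz], axis=1) % 2
    return (parity == 1).reshape(nx, ny, nz)
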