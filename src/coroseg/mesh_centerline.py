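"""Surface meshes, medial-axis centerline and Frenet-Serret frames.

The zero-level surface of a segmentation is triangulated with marching
cubes (on a signed distance map when the input is a binary mask, so the
surface is sub-voxel smooth rather than a voxel staircase). The lumen
centerline is the medial path of the mesh interior: the interior is
voxelized, the Euclidean distance transform gives the inscribed-sphere
radius everywhere, and the centerline is the minimum-cost path between the
two seed points with cost inversely proportional to that radius — a
distance-transform realization of the Voronoi medial axis. The raw medial
path is spline-smoothed (bounded deviation) and resampled at a uniform
arc-length step.

Frames: tangents come from the arc-length derivative. Where curvature is
significant the normal/binormal follow Frenet-Serret; where the curve is
locally straight (curvature below threshold, where Frenet is undefined)
the frame is continued by rotation-minimizing parallel transport.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage
from scipy.interpolate import splev, splprep
from skimage.graph import MCP_Geometric
from skimage.measure import marching_cubes

from .grid import BinaryMask, SeedPoint, Volume


@dataclass
class SurfaceMesh:
    vertices: np.ndarray   # (n, 3) mm
    faces: np.ndarray      # (m, 3) vertex indices
    provenance: str = "lumen"

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @property
    def area(self) -> float:
        return float(self.to_trimesh().area)

    @property
    def enclosed_volume(self) -> float:
        return float(abs(self.to_trimesh().volume))

    @property
    def euler_characteristic(self) -> int:
        return int(self.to_trimesh().euler_number)

    @property
    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    def export(self, path) -> None:
        self.to_trimesh().export(path)


@dataclass
class Centerline:
    points: np.ndarray                  # (n, 3) mm, uniform arc-length step
    arc_length: np.ndarray              # (n,) cumulative mm
    tangent: np.ndarray | None = None
    normal: np.ndarray | None = None
    binormal: np.ndarray | None = None
    max_inscribed_radius: np.ndarray | None = None
    curvature: np.ndarray | None = None

    def __post_init__(self):
        if len(self.points) < 2:
            raise ValueError("centerline needs at least 2 points")
        if np.any(np.linalg.norm(np.diff(self.points, axis=0), axis=1) <= 0):
            raise ValueError("consecutive centerline points must be distinct")

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])

    def to_tsv(self, path) -> None:
        cols = [self.points, self.arc_length[:, None]]
        header = "x\ty\tz\tarclen"
        if self.tangent is not None:
            cols += [self.tangent, self.normal, self.binormal]
            header += "\tTx\tTy\tTz\tNx\tNy\tNz\tBx\tBy\tBz"
        if self.max_inscribed_radius is not None:
            cols.append(self.max_inscribed_radius[:, None])
            header += "\tradius"
        np.savetxt(path, np.hstack(cols), delimiter="\t", header=header, comments="")

    @classmethod
    def from_tsv(cls, path) -> "Centerline":
        arr = np.loadtxt(path, delimiter="\t", skiprows=1)
        cl = cls(points=arr[:, :3], arc_length=arr[:, 3])
        if arr.shape[1] >= 13:
            cl.tangent, cl.normal, cl.binormal = arr[:, 4:7], arr[:, 7:10], arr[:, 10:13]
        if arr.shape[1] >= 14:
            cl.max_inscribed_radius = arr[:, 13]
        return cl


def extract_mesh(mask_or_phi: BinaryMask | Volume, level: float = 0.0,
                 provenance: str = "lumen") -> SurfaceMesh:
    """Marching-cubes isosurface in mm coordinates.

    Binary masks are first converted to a signed Euclidean distance map
    (positive outside) and triangulated at level 0 for a sub-voxel surface.
    """
    if isinstance(mask_or_phi, BinaryMask):
        m = mask_or_phi.data
        if not m.any() or m.all():
            raise ValueError("mask must contain both foreground and background")
        grid = mask_or_phi.grid
        # Gaussian-smoothed occupancy at level 1/2: sub-voxel surface without
        # the staircase bias of meshing the binary lattice directly
        occ = np.pad(m.astype(float), 1)  # pad so boundary-touching masks close
        phi = 0.5 - ndimage.gaussian_filter(occ, sigma=0.8, mode="constant")
        level = 0.0
        shift = -1
    else:
        grid = mask_or_phi.grid
        phi = np.asarray(mask_or_phi.data, float)
        if not (phi.min() < level < phi.max()):
            raise ValueError(f"level {level} outside data range [{phi.min()}, {phi.max()}]")
        phi = np.pad(phi, 1, constant_values=phi.max())
        shift = -1
    verts, faces, _, _ = marching_cubes(phi, level=level, spacing=grid.spacing)
    verts = verts + np.asarray(grid.origin) + shift * np.asarray(grid.spacing)
    return SurfaceMesh(vertices=verts, faces=faces, provenance=provenance)


def _voxelize_interior(mesh: SurfaceMesh, pitch: float):
    """Solid voxelization of a watertight mesh on an isotropic grid.

    The surface is rasterized by supersampling every face below the pitch,
    then the exterior is flood-filled from the bounding-box border; interior
    = not surface and not exterior.
    """
    tm = mesh.to_trimesh()
    lo = tm.bounds[0] - 2 * pitch
    hi = tm.bounds[1] + 2 * pitch
    shape = np.ceil((hi - lo) / pitch).astype(int) + 1

    tris = tm.triangles  # (m, 3, 3)
    # subdivide each triangle into a barycentric point cloud finer than pitch/2
    edge = np.linalg.norm(tris - np.roll(tris, 1, axis=1), axis=2).max()
    n = max(int(np.ceil(edge / (pitch * 0.5))), 1)
    us = []
    for i in range(n + 1):
        for j in range(n + 1 - i):
            us.append((i / n, j / n))
    us = np.asarray(us)
    w = np.stack([1.0 - us[:, 0] - us[:, 1], us[:, 0], us[:, 1]], axis=1)
    pts = np.einsum("kj,mjd->mkd", w, tris).reshape(-1, 3)

    idx = np.round((pts - lo) / pitch).astype(int)
    surf = np.zeros(shape, bool)
    surf[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    outside = np.zeros(shape, bool)
    free = ~surf
    lab, _ = ndimage.label(free)
    border_labels = np.unique(np.concatenate([
        lab[0].ravel(), lab[-1].ravel(), lab[:, 0].ravel(), lab[:, -1].ravel(),
        lab[:, :, 0].ravel(), lab[:, :, -1].ravel()]))
    outside = np.isin(lab, border_labels[border_labels > 0])
    interior = ~surf & ~outside
    return interior, lo, shape


def extract_centerline(mesh: SurfaceMesh, source: SeedPoint, target: SeedPoint,
                       pitch: float = 0.3, resample_step: float = 0.25,
                       max_spline_deviation: float = 0.3) -> Centerline:
    """Medial path between two seeds inside a lumen mesh.

    Minimum-cost path on the interior voxel grid with per-voxel cost
    ``1 / (inscribed radius)``, so the path rides the ridge of the distance
    transform (the medial axis), then spline-smoothed with deviation bounded
    by ``max_spline_deviation`` and resampled uniformly.
    """
    interior, lo, shape = _voxelize_interior(mesh, pitch)
    if not interior.any():
        raise ValueError("mesh has no voxelizable interior at this pitch")
    edt = ndimage.distance_transform_edt(interior, sampling=pitch)

    def to_idx(seed: SeedPoint):
        idx = np.round((np.asarray(seed.position) - lo) / pitch).astype(int)
        if np.any(idx < 0) or np.any(idx >= shape):
            raise ValueError(f"seed {seed.position} outside the mesh bounding box")
        if not interior[tuple(idx)]:
            # snap to the nearest interior voxel within one lumen radius
            r = int(np.ceil(2.0 / pitch))
            win = tuple(slice(max(i - r, 0), min(i + r + 1, s)) for i, s in zip(idx, shape))
            sub = interior[win]
            if not sub.any():
                raise ValueError(f"seed {seed.position} is not inside the mesh")
            cand = np.argwhere(sub) + [w.start for w in win]
            idx = cand[np.argmin(np.linalg.norm((cand - idx) * pitch, axis=1))]
        return tuple(int(v) for v in idx)

    src, tgt = to_idx(source), to_idx(target)
    costs = np.where(interior, 1.0 / (edt + 0.5 * pitch), np.inf)
    mcp = MCP_Geometric(costs, fully_connected=True, sampling=(pitch,) * 3)
    dist, _ = mcp.find_costs([src], [tgt])
    if not np.isfinite(dist[tgt]):
        raise RuntimeError("no interior path between source and target: "
                           "the lumen interior is broken / discontinuous")
    path = np.asarray(mcp.traceback(tgt), float)
    pts = path * pitch + lo

    pts = _smooth_resample(pts, resample_step, max_spline_deviation)
    # inscribed radius from the path to the mesh surface: nearest distance to
    # a dense sample of the surface triangles (exact to the sampling density)
    tm = mesh.to_trimesh()
    surf_pts = tm.triangles.reshape(-1, 3)
    mids = 0.5 * (tm.triangles + np.roll(tm.triangles, 1, axis=1)).reshape(-1, 3)
    cents = tm.triangles.mean(axis=1)
    from scipy.spatial import cKDTree
    tree = cKDTree(np.vstack([surf_pts, mids, cents]))
    radius, _ = tree.query(pts, workers=-1)
    cl = Centerline(points=pts, arc_length=_cumlen(pts), max_inscribed_radius=radius)
    return compute_frames(cl)


def _cumlen(pts: np.ndarray) -> np.ndarray:
    return np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])


def _smooth_resample(pts: np.ndarray, step: float, max_dev: float) -> np.ndarray:
    """Cubic B-spline smoothing with bounded deviation + uniform resampling."""
    keep = np.concatenate([[True], np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9])
    pts = pts[keep]
    n = len(pts)
    if n < 4:
        s_fine = np.linspace(0, 1, max(int(_cumlen(pts)[-1] / step) + 1, 2))
        fine = np.stack([np.interp(s_fine, np.linspace(0, 1, n), pts[:, a]) for a in range(3)], 1)
        return fine
    import warnings
    smooth = n * max_dev ** 2
    for _ in range(12):
        with warnings.catch_warnings():
            # fitpack warns when s is driven small; we control deviation below
            warnings.simplefilter("ignore", RuntimeWarning)
            tck, _ = splprep(pts.T, s=smooth, k=3)
        u = np.linspace(0, 1, 8 * n)
        fine = np.stack(splev(u, tck), axis=1)
        d = np.min(np.linalg.norm(pts[:, None, :] - fine[None, ::8, :], axis=2), axis=1)
        if d.max() <= max_dev or smooth < 1e-8:
            break
        smooth *= 0.25
    s = _cumlen(fine)
    si = np.arange(0.0, s[-1] + 1e-9, step)
    out = np.stack([np.interp(si, s, fine[:, a]) for a in range(3)], axis=1)
    return out


def _transport_normal(prev_n: np.ndarray, t: np.ndarray) -> np.ndarray:
    n = prev_n - t * (prev_n @ t)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        n = _any_perpendicular(t)
        nn = 1.0
    return n / nn


def _any_perpendicular(t: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0]) if abs(t[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    n = np.cross(t, ref)
    return n / np.linalg.norm(n)


def compute_frames(centerline: Centerline, curvature_threshold: float = 1e-4) -> Centerline:
    """Fill tangent/normal/binormal (and curvature) along the centerline.

    Frenet-Serret where curvature >= threshold (with sign continuity
    enforced against the running frame); rotation-minimizing parallel
    transport through straight spans where the Frenet normal is undefined.
    """
    pts = centerline.points
    if len(pts) < 3:
        raise ValueError("need at least 3 points to compute frames")
    s = centerline.arc_length
    d1 = np.gradient(pts, s, axis=0)
    tangent = d1 / np.linalg.norm(d1, axis=1, keepdims=True)
    dT = np.gradient(tangent, s, axis=0)
    curvature = np.linalg.norm(dT, axis=1)

    n = np.empty_like(tangent)
    prev = _any_perpendicular(tangent[0])
    for i in range(len(pts)):
        t = tangent[i]
        if curvature[i] >= curvature_threshold:
            frenet = dT[i] / curvature[i]
            frenet = frenet - t * (frenet @ t)
            nn = np.linalg.norm(frenet)
            if nn > 1e-12:
                frenet /= nn
                if frenet @ _transport_normal(prev, t) < 0:
                    frenet = -frenet  # keep continuity across inflections
                n[i] = frenet
            else:
                n[i] = _transport_normal(prev, t)
        else:
            n[i] = _transport_normal(prev, t)
        prev = n[i]
    b = np.cross(tangent, n)
    b /= np.linalg.norm(b, axis=1, keepdims=True)

    centerline.tangent = tangent
    centerline.normal = n
    centerline.binormal = b
    centerline.curvature = curvature
    return centerline


def parallel_transport_frames(centerline: Centerline) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rotation-minimizing frames (double-reflection) for CMPR sampling.

    Pure parallel transport never spins the cross-section plane along
    straight or low-torsion runs, which Frenet frames do; CMPR uses these.
    """
    pts = centerline.points
    s = centerline.arc_length
    d1 = np.gradient(pts, s, axis=0)
    t = d1 / np.linalg.norm(d1, axis=1, keepdims=True)
    n = np.empty_like(t)
    n[0] = _any_perpendicular(t[0])
    for i in range(1, len(pts)):
        # double-reflection rotation-minimizing frame step
        v1 = pts[i] - pts[i - 1]
        c1 = v1 @ v1
        if c1 < 1e-16:
            n[i] = n[i - 1]
            continue
        rl = n[i - 1] - (2.0 / c1) * (v1 @ n[i - 1]) * v1
        tl = t[i - 1] - (2.0 / c1) * (v1 @ t[i - 1]) * v1
        v2 = t[i] - tl
        c2 = v2 @ v2
        ni = rl if c2 < 1e-16 else rl - (2.0 / c2) * (v2 @ rl) * v2
        ni = ni - t[i] * (ni @ t[i])
        n[i] = ni / np.linalg.norm(ni)
    b = np.cross(t, n)
    b /= np.linalg.norm(b, axis=1, keepdims=True)
    return t, n, b
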