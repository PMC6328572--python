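"""Synthetic coronary CTA phantoms with analytic ground truth.

A phantom is a single vessel following a parametric space curve (line, arc
or helix), with a contrast-filled lumen, a wall of configurable thickness,
optional plaques (soft / calcified / mixed) that narrow the lumen and
thicken the wall, an optional perivascular fat sheath, and a myocardium-like
background. The HU levels follow standard CT tissue ranges: contrast-filled
lumen ~400 HU, soft tissue wall ~50 HU, calcium ~800 HU, fat negative,
myocardium ~40 HU. On top of the clean geometry the generator can apply a
localized anisotropic Gaussian blur (emulating cardiac-motion degradation
over a short arc-length window) and additive Gaussian noise, both seeded.

Ground truth is analytic: masks are noise-free rasterizations of the tube
geometry and reference volumes come from arc-length integration of
``pi * r(s)^2``. Confounder helpers add structures that trip naive
vessel-enhancement approaches (a bright sheet near the vessel, an adjacent
vein at wall-like HU) without touching the truth masks.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter
from scipy.spatial import cKDTree

from .grid import BinaryMask, Grid, Volume


# ---------------------------------------------------------------------------
# Curves

class ParametricCurve:
    """Space curve given by a callable t in [0,1] -> mm point."""

    def __init__(self, fn, n_dense: int = 4097):
        self._fn = fn
        t = np.linspace(0.0, 1.0, n_dense)
        pts = np.asarray([fn(ti) for ti in t], dtype=float)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        self._t = t
        self._pts = pts
        self._s = s

    @property
    def length(self) -> float:
        return float(self._s[-1])

    def sample(self, step: float) -> tuple[np.ndarray, np.ndarray]:
        """Resample uniformly in arc length; returns (points, arc_lengths)."""
        n = max(int(np.ceil(self.length / step)) + 1, 2)
        s = np.linspace(0.0, self.length, n)
        pts = np.empty((n, 3))
        for a in range(3):
            pts[:, a] = np.interp(s, self._s, self._pts[:, a])
        return pts, s

    def tangents(self, pts: np.ndarray) -> np.ndarray:
        t = np.gradient(pts, axis=0)
        return t / np.linalg.norm(t, axis=1, keepdims=True)


def line_curve(start, end) -> ParametricCurve:
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    return ParametricCurve(lambda t: start + t * (end - start), n_dense=257)


def arc_curve(center, radius, angle_span, plane_u=(1, 0, 0), plane_v=(0, 1, 0),
              angle_start=0.0) -> ParametricCurve:
    """Circular arc of `angle_span` radians in the plane spanned by u, v."""
    c = np.asarray(center, float)
    u = np.asarray(plane_u, float)
    v = np.asarray(plane_v, float)
    u = u / np.linalg.norm(u)
    v = v - u * (v @ u)
    v = v / np.linalg.norm(v)

    def fn(t):
        a = angle_start + t * angle_span
        return c + radius * (np.cos(a) * u + np.sin(a) * v)

    return ParametricCurve(fn)


def helix_curve(origin, radius, pitch, turns, phase=0.0) -> ParametricCurve:
    """Helix around the +z axis through `origin`; pitch = axial rise per turn (mm)."""
    o = np.asarray(origin, float)

    def fn(t):
        a = phase + 2.0 * np.pi * turns * t
        return o + np.array([radius * np.cos(a), radius * np.sin(a),
                             pitch * turns * t])

    return ParametricCurve(fn)


# ---------------------------------------------------------------------------
# Specs

class PlaqueType(str, enum.Enum):
    SOFT = "soft"
    CALCIFIED = "calcified"
    MIXED = "mixed"


@dataclass(frozen=True)
class PlaqueSpec:
    """A focal plaque over an arc-length window.

    The lumen radius is multiplied by ``1 - lumen_narrowing_fraction * b(s)``
    and the outer radius increased by ``max_wall_thickening * b(s)`` where
    ``b`` is a raised-cosine bump equal to 1 at the window center and 0 at
    its ends, so profiles stay smooth.
    """

    start_arc_length: float
    length: float
    type: PlaqueType = PlaqueType.SOFT
    max_wall_thickening: float = 1.0
    lumen_narrowing_fraction: float = 0.5

    def __post_init__(self):
        if not (0.0 <= self.lumen_narrowing_fraction < 1.0):
            raise ValueError(
                f"lumen_narrowing_fraction must be in [0,1), got {self.lumen_narrowing_fraction}")
        if self.length <= 0:
            raise ValueError(f"plaque length must be > 0, got {self.length}")

    def bump(self, s: np.ndarray) -> np.ndarray:
        x = (np.asarray(s, float) - self.start_arc_length) / self.length
        b = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.clip(x, 0.0, 1.0)))
        return np.where((x >= 0) & (x <= 1), b, 0.0)


@dataclass(frozen=True)
class HUModel:
    """Tissue attenuation levels in Hounsfield units."""

    lumen_hu: float = 400.0
    wall_hu: float = 50.0
    soft_plaque_hu: float = 50.0
    calcified_plaque_hu: float = 800.0
    fat_hu: float = -80.0
    myocardium_hu: float = 40.0
    background_hu: float = -800.0

    def __post_init__(self):
        if self.fat_hu >= 0:
            raise ValueError(f"fat_hu must be negative, got {self.fat_hu}")
        if self.lumen_hu <= self.wall_hu:
            raise ValueError("lumen_hu must exceed wall_hu")
        if self.calcified_plaque_hu <= self.lumen_hu:
            raise ValueError("calcified_plaque_hu must exceed lumen_hu")


@dataclass
class PhantomSpec:
    """Full description of one synthetic vessel."""

    curve: ParametricCurve
    lumen_radius: float = 1.5            # mm, healthy lumen
    wall_thickness: float = 0.75         # mm, healthy wall (typical reported value)
    plaques: list[PlaqueSpec] = field(default_factory=list)
    hu: HUModel = field(default_factory=HUModel)
    noise_sigma: float = 0.0             # HU
    motion_blur_sigma: tuple[float, float] | None = None  # (in-plane, axial) mm
    motion_blur_window: tuple[float, float] | None = None  # arc length mm
    fat_sheath: bool = True
    fat_gap: float = 0.0                 # mm of soft tissue between wall and fat
    fat_thickness: float = 1.5           # mm
    partial_volume: bool = True          # supersample HU at tissue interfaces
    seed: int = 0

    def __post_init__(self):
        if self.lumen_radius <= 0 or self.wall_thickness < 0:
            raise ValueError("radii must be positive")

    def lumen_radius_at(self, s: np.ndarray) -> np.ndarray:
        r = np.full_like(np.asarray(s, float), self.lumen_radius)
        for p in self.plaques:
            r = r * (1.0 - p.lumen_narrowing_fraction * p.bump(s))
        return r

    def outer_radius_at(self, s: np.ndarray) -> np.ndarray:
        r = np.full_like(np.asarray(s, float), self.lumen_radius + self.wall_thickness)
        for p in self.plaques:
            r = r + p.max_wall_thickening * p.bump(s)
        return r


@dataclass
class PhantomTruth:
    """A rendered phantom plus its analytic ground truth."""

    volume: Volume
    lumen_mask: BinaryMask
    vessel_mask: BinaryMask
    centerline_points: np.ndarray        # (n, 3) mm, uniform arc-length step
    analytic_lumen_volume: float         # mm^3
    analytic_vessel_volume: float        # mm^3
    spec: PhantomSpec
    clean: np.ndarray = None             # noise-free HU lattice

    def seed_near_start(self, offset: float = 1.0):
        """A seed point on the centerline `offset` mm from its start."""
        from .grid import SeedPoint
        step = np.linalg.norm(self.centerline_points[1] - self.centerline_points[0])
        i = min(int(round(offset / step)), len(self.centerline_points) - 1)
        return SeedPoint(tuple(self.centerline_points[i]))

    def seed_near_end(self, offset: float = 1.0):
        from .grid import SeedPoint
        step = np.linalg.norm(self.centerline_points[1] - self.centerline_points[0])
        i = max(len(self.centerline_points) - 1 - int(round(offset / step)), 0)
        return SeedPoint(tuple(self.centerline_points[i]))


# ---------------------------------------------------------------------------
# Rasterization

_SUPERSAMPLE = 3  # sub-voxels per axis for partial-volume rendering


def _tube_coordinates(points, tangents, arclen, query_pts, tree=None):
    """Radial distance and arc length of query points w.r.t. a finite tube.

    Distance to the curve treated as a 1D manifold with flat end caps:
    points whose projection falls beyond either end get an infinite radial
    distance (no spherical caps).
    """
    if tree is None:
        tree = cKDTree(points)
    d, idx = tree.query(query_pts, workers=-1)
    delta = query_pts - points[idx]
    axial = np.einsum("ij,ij->i", delta, tangents[idx])
    rad2 = np.maximum(np.einsum("ij,ij->i", delta, delta) - axial ** 2, 0.0)
    d_rad = np.sqrt(rad2)
    s = arclen[idx]
    step = arclen[1] - arclen[0]
    beyond = ((idx == 0) & (axial < -0.5 * step)) | \
             ((idx == len(points) - 1) & (axial > 0.5 * step))
    d_rad = np.where(beyond, np.inf, d_rad)
    return d_rad, s


def _render_hu(spec: PhantomSpec, d, s):
    """Noise-free HU for points at radial distance d / arc length s."""
    hu = spec.hu
    r_l = spec.lumen_radius_at(s)
    r_o = spec.outer_radius_at(s)
    out = np.full(d.shape, hu.myocardium_hu)
    if spec.fat_sheath:
        fat_in = r_o + spec.fat_gap
        in_fat = (d > fat_in) & (d <= fat_in + spec.fat_thickness)
        out[in_fat] = hu.fat_hu
    in_wall = (d > r_l) & (d <= r_o)
    out[in_wall] = hu.wall_hu
    for p in spec.plaques:
        b = p.bump(s)
        window = in_wall & (b > 1e-6)
        if p.type is PlaqueType.SOFT:
            out[window] = hu.soft_plaque_hu
        elif p.type is PlaqueType.CALCIFIED:
            out[window] = hu.calcified_plaque_hu
        else:  # mixed: calcified core toward the lumen, soft shoulder outside
            mid = 0.5 * (r_l + r_o)
            out[window & (d <= mid)] = hu.calcified_plaque_hu
            out[window & (d > mid)] = hu.soft_plaque_hu
    out[d <= r_l] = hu.lumen_hu
    return out


def make_phantom(spec: PhantomSpec, shape, spacing, origin=(0.0, 0.0, 0.0)) -> PhantomTruth:
    """Rasterize a PhantomSpec onto a lattice.

    Voxels are labelled by radial distance to the curve; HU values are
    supersampled 3x per axis near the vessel and averaged (partial-volume
    rendering), then the optional motion blur and seeded Gaussian noise are
    applied. Masks are noise-free center-sample rasterizations. Analytic
    volumes integrate ``pi r(s)^2 ds`` along the curve.
    """
    grid = Grid(tuple(int(n) for n in shape), tuple(float(sp) for sp in spacing),
                tuple(float(o) for o in origin))
    spacing = np.asarray(grid.spacing)
    step = float(min(spacing)) / 4.0
    pts, arclen = spec.curve.sample(step)
    tangents = spec.curve.tangents(pts)

    low, high = grid.physical_bounds()
    r_out_max = float(spec.outer_radius_at(arclen).max())
    # the curve itself must stay on-lattice; the tube cross-section may be
    # clipped at the faces (face-to-face vessels have no end caps in-volume)
    off = np.linalg.norm(pts - np.clip(pts, low, high), axis=1)
    if np.any(off > 1e-9):
        raise ValueError("centerline curve exits the volume bounds")

    tree = cKDTree(pts)
    idx_grid = np.stack(np.meshgrid(*[np.arange(n) for n in grid.shape], indexing="ij"),
                        axis=-1).reshape(-1, 3).astype(float)
    centers = grid.index_to_physical(idx_grid)
    d, s = _tube_coordinates(pts, tangents, arclen, centers, tree)

    r_l = spec.lumen_radius_at(s)
    r_o = spec.outer_radius_at(s)
    lumen = (d <= r_l).reshape(grid.shape)
    vessel = (d <= r_o).reshape(grid.shape)

    clean = _render_hu(spec, d, s).reshape(grid.shape)

    # partial-volume supersampling in a shell around the vessel + fat sheath
    reach = r_out_max + (spec.fat_gap + spec.fat_thickness if spec.fat_sheath else 0.0)
    near = (d <= reach + 1.5 * float(max(spacing))) & (d >= 0) \
        if spec.partial_volume else np.zeros_like(d, bool)
    near_idx = idx_grid[near]
    if near_idx.size:
        offs = (np.arange(_SUPERSAMPLE) + 0.5) / _SUPERSAMPLE - 0.5
        sub = np.stack(np.meshgrid(offs, offs, offs, indexing="ij"), axis=-1).reshape(-1, 3)
        acc = np.zeros(len(near_idx))
        for o in sub:
            q = grid.index_to_physical(near_idx + o)
            dd, ss = _tube_coordinates(pts, tangents, arclen, q, tree)
            acc += _render_hu(spec, dd, ss)
        flat = clean.reshape(-1)
        flat[near.nonzero()[0]] = acc / len(sub)
        clean = flat.reshape(grid.shape)

    if spec.motion_blur_sigma is not None:
        clean = _apply_motion_blur(clean, grid, spec, s.reshape(grid.shape), d.reshape(grid.shape))

    rng = np.random.default_rng(spec.seed)
    noisy = clean + (rng.normal(0.0, spec.noise_sigma, grid.shape)
                     if spec.noise_sigma > 0 else 0.0)

    cl_pts, _ = spec.curve.sample(0.25)
    r2 = spec.lumen_radius_at(arclen) ** 2
    analytic_lumen = float(np.trapezoid(np.pi * r2, arclen))
    analytic_vessel = float(np.trapezoid(np.pi * spec.outer_radius_at(arclen) ** 2, arclen))

    return PhantomTruth(
        volume=Volume(noisy, grid),
        lumen_mask=BinaryMask(lumen, grid),
        vessel_mask=BinaryMask(vessel, grid),
        centerline_points=cl_pts,
        analytic_lumen_volume=analytic_lumen,
        analytic_vessel_volume=analytic_vessel,
        spec=spec,
        clean=clean,
    )


def _apply_motion_blur(clean, grid, spec, s_field, d_field):
    """Blend in an anisotropically blurred copy over the stated arc window."""
    sig_inplane, sig_axial = spec.motion_blur_sigma
    sigma_vox = np.array([sig_inplane, sig_inplane, sig_axial]) / np.asarray(grid.spacing)
    blurred = gaussian_filter(clean, sigma=sigma_vox, mode="nearest")
    if spec.motion_blur_window is None:
        return blurred
    s0, s1 = spec.motion_blur_window
    ramp = 1.0  # mm of cosine transition at the window edges
    x = np.clip(np.minimum(s_field - s0, s1 - s_field) / ramp, 0.0, 1.0)
    w = 0.5 * (1.0 - np.cos(np.pi * x))
    w[(s_field < s0) | (s_field > s1)] = 0.0
    return clean * (1.0 - w) + blurred * w


def _renoise(truth: PhantomTruth) -> np.ndarray:
    rng = np.random.default_rng(truth.spec.seed)
    if truth.spec.noise_sigma > 0:
        return truth.clean + rng.normal(0.0, truth.spec.noise_sigma, truth.clean.shape)
    return truth.clean.copy()


def confounder_bright_sheet(truth: PhantomTruth, offset: float, hu: float = 400.0,
                            thickness: float = 0.8,
                            width: float | None = None) -> PhantomTruth:
    """Insert a thin bright sheet near (but disjoint from) the vessel.

    The sheet is normal to +x, placed `offset` mm beyond the vessel's
    maximal x extent, running the full z extent. ``width`` limits its y
    extent (centered on the vessel); a finite-width ribbon has a rod-like
    cross-section and is strongly vessel-enhanced, emulating the elongated
    interface structures that confound tube filters. ``width=None`` gives a
    full plane. Ground-truth masks are untouched.
    """
    grid = truth.volume.grid
    vx = truth.vessel_mask.data
    sampling = grid.spacing
    dist_out = distance_transform_edt(~vx, sampling=sampling)

    xs = grid.index_to_physical(np.stack([np.arange(grid.shape[0]),
                                          np.zeros(grid.shape[0]),
                                          np.zeros(grid.shape[0])], axis=-1))[:, 0]
    x_max = xs[np.any(vx, axis=(1, 2))].max()
    lo, hi = x_max + offset, x_max + offset + thickness
    sheet = ((xs >= lo) & (xs <= hi))[:, None, None] & np.ones(grid.shape, bool)
    if width is not None:
        ys = grid.index_to_physical(np.stack([np.zeros(grid.shape[1]),
                                              np.arange(grid.shape[1]),
                                              np.zeros(grid.shape[1])], axis=-1))[:, 1]
        jj = np.argwhere(np.any(vx, axis=(0, 2)))
        y_mid = 0.5 * (ys[jj.min()] + ys[jj.max()])
        in_y = np.abs(ys - y_mid) <= width / 2.0
        sheet &= in_y[None, :, None]
    if not sheet.any():
        raise ValueError("bright sheet falls outside the volume; reduce offset")
    if np.any(sheet & vx) or dist_out[sheet].min() <= 0:
        raise ValueError("bright sheet would intersect the vessel")

    clean = truth.clean.copy()
    clean[sheet] = hu
    new = PhantomTruth(volume=truth.volume, lumen_mask=truth.lumen_mask,
                       vessel_mask=truth.vessel_mask,
                       centerline_points=truth.centerline_points,
                       analytic_lumen_volume=truth.analytic_lumen_volume,
                       analytic_vessel_volume=truth.analytic_vessel_volume,
                       spec=truth.spec, clean=clean)
    new.volume = Volume(_renoise(new), grid)
    new.sheet_mask = BinaryMask(sheet, grid)
    return new


def confounder_adjacent_vein(truth: PhantomTruth, gap: float,
                             vein_radius: float = 1.5) -> PhantomTruth:
    """Add a parallel tube at wall-like HU at surface-to-surface `gap` mm.

    Emulates a coronary vein hugging the artery; at gap 0 the structures
    touch and outer-wall segmentation is expected to bleed into the vein.
    Truth masks are unchanged.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    grid = truth.volume.grid
    spec = truth.spec
    step = float(min(grid.spacing)) / 4.0
    pts, arclen = spec.curve.sample(step)
    tangents = spec.curve.tangents(pts)
    t_mean = tangents.mean(axis=0)
    t_mean /= np.linalg.norm(t_mean)
    perp = np.cross(t_mean, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(t_mean, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    r_out = float(spec.outer_radius_at(arclen).max())
    shift = perp * (r_out + gap + vein_radius)
    vein_pts = pts + shift

    idx_grid = np.stack(np.meshgrid(*[np.arange(n) for n in grid.shape], indexing="ij"),
                        axis=-1).reshape(-1, 3).astype(float)
    centers = grid.index_to_physical(idx_grid)
    d, _ = _tube_coordinates(vein_pts, tangents, arclen, centers)
    vein = (d <= vein_radius).reshape(grid.shape)
    clean = truth.clean.copy()
    vein_only = vein & ~truth.vessel_mask.data
    clean[vein_only] = spec.hu.wall_hu

    new = PhantomTruth(volume=truth.volume, lumen_mask=truth.lumen_mask,
                       vessel_mask=truth.vessel_mask,
                       centerline_points=truth.centerline_points,
                       analytic_lumen_volume=truth.analytic_lumen_volume,
                       analytic_vessel_volume=truth.analytic_vessel_volume,
                       spec=truth.spec, clean=clean)
    new.volume = Volume(_renoise(new), grid)
    new.vein_mask = BinaryMask(vein_only, grid)
    return new
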