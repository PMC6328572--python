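"""Curved multiplanar reformation: vessel straightening and wall profiling.

Each centerline point carries a cross-section plane spanned by the
rotation-minimizing normal/binormal (parallel-transport frames, so the
in-plane orientation does not spin along straight runs). The volume is
resampled on those planes into a straightened stack whose axis 0 is arc
length; HU volumes use trilinear interpolation, masks nearest-neighbor so
they stay binary. Radial longitudinal sections and the per-slice wall
thickness profile are computed on the straightened stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import BinaryMask, Volume
from .mesh_centerline import Centerline, parallel_transport_frames

OOB_SENTINEL = -2000.0  # HU fill for samples outside the source volume


@dataclass
class StraightenedVolume:
    data: np.ndarray              # (n_slices, n_u, n_v); axis 0 = arc length
    arc_length: np.ndarray        # (n_slices,) mm
    in_plane_step: float          # mm
    half_width: float             # mm
    centerline: Centerline
    interpolation: str            # "linear" | "nearest"
    oob_slices: np.ndarray        # per-slice flag: any out-of-bounds sample

    @property
    def center_index(self) -> int:
        return (self.data.shape[1] - 1) // 2

    def as_mask_stack(self) -> np.ndarray:
        return self.data > 0.5


@dataclass
class WallThicknessProfile:
    arc_length: np.ndarray        # mm per slice
    mean_thickness: np.ndarray    # mm per slice (NaN where lumen missing)
    lumen_area: np.ndarray        # mm^2
    vessel_area: np.ndarray       # mm^2
    missing: np.ndarray           # slices with empty lumen

    def to_tsv(self, path) -> None:
        np.savetxt(path, np.stack([self.arc_length, self.mean_thickness,
                                   self.lumen_area, self.vessel_area], axis=1),
                   delimiter="\t", header="arclen\tmean_thickness\tlumen_area\tvessel_area",
                   comments="")


def straighten(volume: Volume | BinaryMask, centerline: Centerline,
               half_width: float = 10.0, in_plane_step: float = 0.2,
               interpolation: str | None = None) -> StraightenedVolume:
    """Resample a volume (or mask) on planes normal to the centerline."""
    if half_width <= 0:
        raise ValueError("half_width must be > 0")
    is_mask = isinstance(volume, BinaryMask)
    if interpolation is None:
        interpolation = "nearest" if is_mask else "linear"
    order = 0 if interpolation == "nearest" else 1

    t, n, b = parallel_transport_frames(centerline)
    m = 2 * int(round(half_width / in_plane_step)) + 1
    offs = (np.arange(m) - (m - 1) / 2) * in_plane_step
    uu, vv = np.meshgrid(offs, offs, indexing="ij")

    pts = (centerline.points[:, None, None, :]
           + uu[None, :, :, None] * n[:, None, None, :]
           + vv[None, :, :, None] * b[:, None, None, :])
    idx, inside = volume.grid.physical_to_index(pts.reshape(-1, 3))
    data = volume.data.astype(float)
    cval = 0.0 if is_mask else OOB_SENTINEL
    samp = ndimage.map_coordinates(data, idx.T, order=order, mode="constant", cval=cval)
    samp = samp.reshape(len(centerline.points), m, m)
    oob = ~inside.reshape(len(centerline.points), m, m)

    return StraightenedVolume(data=samp, arc_length=centerline.arc_length.copy(),
                              in_plane_step=float(in_plane_step), half_width=float(half_width),
                              centerline=centerline, interpolation=interpolation,
                              oob_slices=oob.any(axis=(1, 2)))


def radial_sections(straight: StraightenedVolume, n_sections: int,
                    order: int | None = None) -> list[np.ndarray]:
    """Longitudinal sections through the centerline column.

    Section k lies at angle ``k * (180 deg / n_sections)``; 5 sections give
    the 36-degree gap of the reader protocol, 20 give 9 degrees. Each
    section is (arc length x diameter).
    """
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    if order is None:
        order = 0 if straight.interpolation == "nearest" else 1
    n, m, _ = straight.data.shape
    c = (m - 1) / 2
    ts = np.arange(m) - c  # in-plane offsets in steps
    out = []
    for k in range(n_sections):
        theta = np.deg2rad(k * 180.0 / n_sections)
        iu = c + ts * np.cos(theta)
        iv = c + ts * np.sin(theta)
        coords = np.stack([np.repeat(np.arange(n), m),
                           np.tile(iu, n), np.tile(iv, n)])
        sec = ndimage.map_coordinates(straight.data, coords, order=order,
                                      mode="nearest").reshape(n, m)
        out.append(sec)
    return out


def section_angles_deg(n_sections: int) -> np.ndarray:
    """Angular positions of the radial sections, in degrees."""
    return np.arange(n_sections) * 180.0 / n_sections


def wall_thickness_profile(straight_lumen: StraightenedVolume,
                           straight_vessel: StraightenedVolume,
                           n_rays: int = 360,
                           method: str = "ray") -> WallThicknessProfile:
    """Per-slice mean wall thickness and lumen/vessel areas.

    ``method="ray"``: thickness is the mean over rays from the centerline of
    (outer boundary radius - lumen boundary radius), the boundary radius
    being the outermost sample on the ray inside the respective mask.
    ``method="area"``: thickness of the area-equivalent circular annulus.
    """
    if straight_lumen.data.shape != straight_vessel.data.shape:
        raise ValueError("straightened lumen and vessel grids differ")
    step = straight_lumen.in_plane_step
    lum = straight_lumen.as_mask_stack()
    ves = straight_vessel.as_mask_stack() | lum
    n, m, _ = lum.shape
    lumen_area = lum.sum(axis=(1, 2)) * step ** 2
    vessel_area = ves.sum(axis=(1, 2)) * step ** 2
    missing = ~lum.any(axis=(1, 2))

    if method == "area":
        thick = np.sqrt(vessel_area / np.pi) - np.sqrt(lumen_area / np.pi)
        thick = np.where(missing, np.nan, thick)
        return WallThicknessProfile(straight_lumen.arc_length.copy(), thick,
                                    lumen_area, vessel_area, missing)

    c = (m - 1) / 2
    radii = np.arange(0.0, straight_lumen.half_width + 1e-9, step / 2.0)
    angles = np.linspace(0.0, 2 * np.pi, n_rays, endpoint=False)
    iu = c + np.outer(np.cos(angles), radii) / step   # (n_rays, n_r)
    iv = c + np.outer(np.sin(angles), radii) / step
    thick = np.full(n, np.nan)
    for i in range(n):
        if missing[i]:
            continue
        lslice = ndimage.map_coordinates(lum[i].astype(np.uint8), [iu, iv],
                                         order=0, mode="constant") > 0
        vslice = ndimage.map_coordinates(ves[i].astype(np.uint8), [iu, iv],
                                         order=0, mode="constant") > 0
        r_l = _outermost_radius(lslice, radii)
        r_v = _outermost_radius(vslice, radii)
        ok = ~np.isnan(r_v)
        r_l = np.where(np.isnan(r_l), 0.0, r_l)
        if ok.any():
            thick[i] = np.clip(r_v[ok] - r_l[ok], 0.0, None).mean()
    return WallThicknessProfile(straight_lumen.arc_length.copy(), thick,
                                lumen_area, vessel_area, missing)


def _outermost_radius(hits: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Outermost radius with a mask hit per ray; NaN where the ray misses."""
    any_hit = hits.any(axis=1)
    last = hits.shape[1] - 1 - np.argmax(hits[:, ::-1], axis=1)
    return np.where(any_hit, radii[last], np.nan)
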