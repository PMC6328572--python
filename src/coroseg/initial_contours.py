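"""Robust initial contours for the dual level-set segmentation.

Two ideas carry this stage:

* The lumen initial contour is the voxelwise intersection of two seeded
  region growings — one on the HU image (which alone would leak into the
  aorta and any connected blood-pool voxels) and one on the vesselness
  image (which alone picks up tube-like confounders such as heart-lung
  interfaces). The intersection keeps only structures that are both
  HU-connected to the seed and tube-shaped.

* The outer-wall initial contour extends the segmented lumen outward by a
  fixed geodesic distance (default 5.5 mm, sized to contain the thickest
  reported plaques), propagating only through non-fat tissue: voxels with
  negative HU act as barriers, so perivascular fat bounds the dilation
  instead of merely being masked out afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.graph import MCP_Geometric

from .grid import BinaryMask, SeedPoint, Volume
from .vesselness import VesselnessImage


@dataclass
class RegionGrowParams:
    lower_threshold: float
    upper_threshold: float
    connectivity: int = 26

    def __post_init__(self):
        if self.lower_threshold > self.upper_threshold:
            raise ValueError("lower_threshold must be <= upper_threshold")
        if self.connectivity not in (6, 26):
            raise ValueError(f"connectivity must be 6 or 26, got {self.connectivity}")


@dataclass
class OuterInitParams:
    dilation_distance: float = 5.5   # mm; sized to the thickest reported plaques
    fat_hu_threshold: float = 0.0    # voxels below this HU block propagation
    connectivity: int = 26

    def __post_init__(self):
        if self.dilation_distance <= 0:
            raise ValueError("dilation_distance must be > 0")


def _seed_indices(image, seeds: list[SeedPoint]) -> list[tuple[int, int, int]]:
    out = []
    for seed in seeds:
        seed.validate_in(image.grid)
        idx, _ = image.grid.physical_to_index(seed.position)
        out.append(tuple(int(round(v)) for v in np.clip(idx, 0, np.asarray(image.grid.shape) - 1)))
    return out


class SeedRejectionError(ValueError):
    """A seed voxel's value falls outside the region-growing window."""


class EmptyIntersectionError(RuntimeError):
    """HU and vesselness region growings share no voxels: initialization failed."""


def region_grow(image: Volume | VesselnessImage, seeds: list[SeedPoint],
                params: RegionGrowParams) -> BinaryMask:
    """Seeded connected-threshold growing.

    Returns the union of connected components of
    ``lower <= value <= upper`` that contain at least one seed.
    """
    if not seeds:
        raise ValueError("at least one seed is required")
    data = image.data
    in_range = (data >= params.lower_threshold) & (data <= params.upper_threshold)
    idxs = _seed_indices(image, seeds)
    for seed, idx in zip(seeds, idxs):
        if not in_range[idx]:
            raise SeedRejectionError(
                f"seed {seed.label.value} at {seed.position} mm has value "
                f"{data[idx]:.6g}, outside [{params.lower_threshold}, {params.upper_threshold}]")
    structure = ndimage.generate_binary_structure(3, 1 if params.connectivity == 6 else 3)
    labels, _ = ndimage.label(in_range, structure=structure)
    keep = {labels[idx] for idx in idxs}
    keep.discard(0)
    mask = np.isin(labels, sorted(keep))
    return BinaryMask(mask, image.grid)


def lumen_initial_contour(volume: Volume, ves: VesselnessImage, seeds: list[SeedPoint],
                          hu_params: RegionGrowParams,
                          ves_params: RegionGrowParams) -> BinaryMask:
    """S1: intersect HU region growing with vesselness region growing."""
    hu_mask = region_grow(volume, seeds, hu_params)
    ves_mask = region_grow(ves, seeds, ves_params)
    inter = hu_mask.data & ves_mask.data
    if not inter.any():
        raise EmptyIntersectionError(
            "HU and vesselness region growings do not overlap; revise the "
            f"thresholds (HU window [{hu_params.lower_threshold}, {hu_params.upper_threshold}], "
            f"vesselness window [{ves_params.lower_threshold}, {ves_params.upper_threshold}])")
    return BinaryMask(inter, volume.grid)


def _chamfer_slack(spacing, connectivity: int) -> float:
    """Worst-case ratio of the discrete path metric to Euclidean distance.

    The discrete unit ball is the convex hull of the normalized step
    vectors; its inradius r gives the certified bound
    ``chamfer <= euclidean / r`` over all directions (anisotropy included).
    """
    from scipy.spatial import ConvexHull

    offs = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                if connectivity == 6 and abs(di) + abs(dj) + abs(dk) != 1:
                    continue
                offs.append((di, dj, dk))
    steps = np.asarray(offs, float) * np.asarray(spacing, float)
    pts = steps / np.linalg.norm(steps, axis=1, keepdims=True)
    hull = ConvexHull(pts)
    inradius = np.abs(hull.equations[:, 3]).min()
    return float(1.0 / inradius)


def geodesic_distance(domain: np.ndarray, sources: np.ndarray, spacing,
                      connectivity: int = 26) -> np.ndarray:
    """Geodesic distance (mm) from sources propagating only through domain.

    Returns a certified lower bound on the continuous geodesic distance
    that is *exact* (equal to the Euclidean distance transform) wherever a
    source sees the voxel along an unobstructed straight segment:

    * reachability is 6-connected flood fill within the domain, so a
      face-connected closed barrier (e.g. an enclosing fat sheath) is
      never crossed, not even through diagonal pinholes;
    * within the reachable region the distance is
      ``max(EDT, chamfer / slack)`` where EDT is the exact Euclidean
      distance to the sources (a lower bound on any geodesic) and
      chamfer is the discrete shortest path, divided by its worst-case
      direction-dependent overestimation factor.

    Voxels outside the domain or unreachable get +inf.
    """
    spacing = tuple(float(s) for s in spacing)
    allowed = domain | sources
    # 6-connected reachability: barrier-tight
    structure = ndimage.generate_binary_structure(3, 1)
    lab, _ = ndimage.label(allowed, structure=structure)
    reach_labels = np.unique(lab[sources])
    reach_labels = reach_labels[reach_labels > 0]
    reachable = np.isin(lab, reach_labels)

    costs = np.where(reachable, 1.0, np.inf)
    mcp = MCP_Geometric(costs, fully_connected=(connectivity == 26), sampling=spacing)
    dist_chamfer, _ = mcp.find_costs(np.argwhere(sources))
    edt = ndimage.distance_transform_edt(~sources, sampling=spacing)
    dist = np.maximum(edt, dist_chamfer / _chamfer_slack(spacing, connectivity))
    dist[~reachable] = np.inf
    dist[sources] = 0.0
    return dist


def outer_initial_contour(lumen_final: BinaryMask, volume: Volume,
                          params: OuterInitParams | None = None) -> BinaryMask:
    """S2: restricted (geodesic) dilation of the lumen by a fixed mm distance.

    The propagation domain is ``{HU >= fat_hu_threshold} | lumen``; fat
    voxels are barriers, so the dilation cannot leak across an enclosing
    fat sheath. Output always contains the lumen.
    """
    params = params or OuterInitParams()
    if not lumen_final.data.any():
        raise ValueError("lumen mask is empty")
    domain = (volume.data >= params.fat_hu_threshold) | lumen_final.data
    dist = geodesic_distance(domain, lumen_final.data, volume.grid.spacing,
                             params.connectivity)
    out = (dist <= params.dilation_distance) | lumen_final.data
    return BinaryMask(out, volume.grid)


def default_vesselness_window(ves: VesselnessImage, top_fraction: float = 0.02
                              ) -> RegionGrowParams:
    """Region-growing window keeping the top fraction of nonzero vesselness."""
    nz = ves.data[ves.data > 0]
    if nz.size == 0:
        raise ValueError("vesselness image is identically zero")
    lo = float(np.quantile(nz, 1.0 - top_fraction))
    return RegionGrowParams(lower_threshold=lo, upper_threshold=float(np.inf))
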