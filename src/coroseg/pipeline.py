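"""End-to-end orchestration: S1 -> S3 -> S2 -> S4 -> meshes -> centerline -> CMPR.

Stage order matches the framework design: vesselness, intersected lumen
initial contour (S1), outward lumen level set (S3), restricted dilation
from the final lumen (S2), inward vessel level set (S4), wall join, then
the visualization chain (meshes, medial centerline, straightening,
thickness profile). Runtime contracts are asserted between stages
(outer initial contains the lumen; vessel contains lumen; wall = vessel
minus lumen) and every stage's output is hashed for reproducibility checks.

A test-only ``initial_mode="seed_sphere"`` replaces S1 with a small sphere
around the first seed — the naive initialization that motivates the robust
initial contour; it exists to demonstrate the failure mode, not for use.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from .cmpr import StraightenedVolume, WallThicknessProfile, straighten, wall_thickness_profile
from .grid import BinaryMask, SeedPoint, Volume
from .initial_contours import (OuterInitParams, RegionGrowParams, default_vesselness_window,
                               lumen_initial_contour, outer_initial_contour, region_grow)
from .levelset import (LevelSetParams, WallSegmentation, segment_boundary, segment_wall)
from .mesh_centerline import Centerline, SurfaceMesh, extract_centerline, extract_mesh
from .vesselness import VesselnessParams, frangi_vesselness


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    vesselness: VesselnessParams = field(default_factory=VesselnessParams)
    hu_grow: RegionGrowParams = field(
        default_factory=lambda: RegionGrowParams(175.0, 800.0))
    vesselness_top_fraction: float = 0.02   # region-grow keeps this top slice
    outer_init: OuterInitParams = field(default_factory=OuterInitParams)
    lumen_levelset: LevelSetParams = field(
        default_factory=lambda: LevelSetParams(gradient_sigma=0.4, propagation_weight=1.0,
                                               advection_weight=1.0, max_iterations=150))
    vessel_levelset: LevelSetParams = field(
        default_factory=lambda: LevelSetParams(gradient_sigma=0.5, propagation_weight=-1.0,
                                               advection_weight=0.0, max_iterations=150))
    lumen_supersample: int = 3              # sub-voxel front placement factor
    vessel_supersample: int = 2
    levelset_margin: float = 4.0            # mm crop margin around initial contours
    centerline_pitch: float = 0.3           # mm voxelization pitch for the medial axis
    centerline_step: float = 0.25           # mm resample step
    cmpr_half_width: float = 10.0           # mm
    cmpr_in_plane_step: float = 0.2         # mm
    min_caliber_mm: float = 2.0             # QC: flag spans below this diameter
    stenosis_windows: list = field(default_factory=list)  # [(start_mm, end_mm)] exempt from QC
    seed_sphere_radius: float = 1.0         # mm, naive-baseline initializer

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        raw = yaml.safe_load(text) or {}
        kwargs = {}
        blocks = {"vesselness": VesselnessParams, "hu_grow": RegionGrowParams,
                  "outer_init": OuterInitParams, "lumen_levelset": LevelSetParams,
                  "vessel_levelset": LevelSetParams}
        for key, val in raw.items():
            if key in blocks:
                if key == "vesselness" and isinstance(val.get("scales"), list):
                    val["scales"] = tuple(val["scales"])
                kwargs[key] = blocks[key](**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)


@dataclass
class RunRecord:
    config: dict
    timings: dict = field(default_factory=dict)
    hashes: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"config": self.config, "timings": self.timings,
                "hashes": self.hashes, "qc": self.qc}


@dataclass
class PipelineResult:
    wall: WallSegmentation
    lumen_initial: BinaryMask
    outer_initial: BinaryMask
    lumen_mesh: SurfaceMesh | None
    vessel_mesh: SurfaceMesh | None
    centerline: Centerline | None
    straight_volume: StraightenedVolume | None
    straight_lumen: StraightenedVolume | None
    straight_vessel: StraightenedVolume | None
    thickness: WallThicknessProfile | None
    record: RunRecord


def _hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _seed_sphere(volume: Volume, seed: SeedPoint, radius: float) -> BinaryMask:
    idx = np.stack(np.meshgrid(*[np.arange(n) for n in volume.grid.shape],
                               indexing="ij"), axis=-1)
    centers = volume.grid.index_to_physical(idx.reshape(-1, 3))
    d = np.linalg.norm(centers - np.asarray(seed.position), axis=1)
    return BinaryMask((d <= radius).reshape(volume.grid.shape), volume.grid)


def run_pipeline(volume: Volume, seeds: list[SeedPoint],
                 config: PipelineConfig | None = None,
                 initial_mode: str = "s1",
                 visualize: bool = True) -> PipelineResult:
    """Run the full framework on one branch (source seed -> optional target).

    ``seeds[0]`` is the ostium (region-growing source); ``seeds[1]``, when
    given, is the distal target that closes the centerline path. Without a
    target the visualization stages are skipped and flagged in QC.
    """
    config = config or PipelineConfig()
    if not seeds:
        raise StageError("setup", "at least one seed is required")
    for s in seeds:
        s.validate_in(volume.grid)
    record = RunRecord(config=yaml.safe_load(config.to_yaml()))
    t_all = time.perf_counter()

    def timed(stage, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
        record.timings[stage] = time.perf_counter() - t0
        return out

    ves = timed("vesselness", lambda: frangi_vesselness(volume, config.vesselness))
    record.hashes["vesselness"] = _hash(ves.data)

    if initial_mode == "seed_sphere":
        s1 = timed("lumen_initial", lambda: _seed_sphere(volume, seeds[0],
                                                         config.seed_sphere_radius))
    else:
        def _s1():
            win = default_vesselness_window(ves, config.vesselness_top_fraction)
            return lumen_initial_contour(volume, ves, seeds, config.hu_grow, win)
        s1 = timed("lumen_initial", _s1)
    record.hashes["lumen_initial"] = _hash(s1.data)

    lumen_final = timed("lumen_levelset", lambda: segment_boundary(
        volume, s1, config.lumen_levelset, supersample=config.lumen_supersample,
        margin=config.levelset_margin))
    record.qc["lumen_levelset_converged"] = bool(getattr(lumen_final, "converged", True))
    record.hashes["lumen_final"] = _hash(lumen_final.data)

    s2 = timed("outer_initial", lambda: outer_initial_contour(lumen_final, volume,
                                                              config.outer_init))
    if np.any(lumen_final.data & ~s2.data):
        raise StageError("outer_initial", "outer initial contour does not contain the lumen")
    record.hashes["outer_initial"] = _hash(s2.data)

    vessel_final = timed("vessel_levelset", lambda: segment_boundary(
        volume, s2, config.vessel_levelset, supersample=config.vessel_supersample,
        margin=2.0))
    record.qc["vessel_levelset_converged"] = bool(getattr(vessel_final, "converged", True))

    wall = timed("wall_join", lambda: segment_wall(lumen_final, vessel_final))
    record.hashes["lumen"] = _hash(wall.lumen.data)
    record.hashes["vessel"] = _hash(wall.vessel.data)
    record.hashes["wall"] = _hash(wall.wall.data)

    lumen_mesh = vessel_mesh = centerline = None
    st_vol = st_lum = st_ves = thickness = None
    if visualize:
        lumen_mesh = timed("lumen_mesh", lambda: extract_mesh(wall.lumen, provenance="lumen"))
        vessel_mesh = timed("vessel_mesh", lambda: extract_mesh(wall.vessel, provenance="vessel"))
        if len(seeds) >= 2:
            try:
                centerline = timed("centerline", lambda: extract_centerline(
                    lumen_mesh, seeds[0], seeds[-1], pitch=config.centerline_pitch,
                    resample_step=config.centerline_step))
            except (RuntimeError, ValueError) as exc:
                record.qc["centerline_failure"] = str(exc)
        else:
            record.qc["centerline_skipped"] = "no distal target seed given"
        if centerline is not None:
            st_vol = timed("cmpr_volume", lambda: straighten(
                volume, centerline, config.cmpr_half_width, config.cmpr_in_plane_step))
            st_lum = timed("cmpr_lumen", lambda: straighten(
                wall.lumen, centerline, config.cmpr_half_width, config.cmpr_in_plane_step))
            st_ves = timed("cmpr_vessel", lambda: straighten(
                wall.vessel, centerline, config.cmpr_half_width, config.cmpr_in_plane_step))
            record.qc["cmpr_oob_slices"] = int(st_vol.oob_slices.sum())
            thickness = timed("thickness", lambda: wall_thickness_profile(st_lum, st_ves))
            record.qc["caliber_flags"] = qc_caliber_flags(
                st_lum, config.min_caliber_mm, config.stenosis_windows)

    record.timings["total"] = time.perf_counter() - t_all
    return PipelineResult(wall=wall, lumen_initial=s1, outer_initial=s2,
                          lumen_mesh=lumen_mesh, vessel_mesh=vessel_mesh,
                          centerline=centerline, straight_volume=st_vol,
                          straight_lumen=st_lum, straight_vessel=st_ves,
                          thickness=thickness, record=record)


def qc_caliber_flags(straight_lumen: StraightenedVolume, min_caliber: float = 2.0,
                     stenosis_windows=()) -> list[tuple[float, float]]:
    """Arc-length spans whose area-equivalent lumen diameter is sub-caliber.

    Spans that fall entirely inside a declared focal-stenosis window are
    exempt (focal narrowing is disease to be measured, not a quality flag).
    """
    lum = straight_lumen.as_mask_stack()
    area = lum.sum(axis=(1, 2)) * straight_lumen.in_plane_step ** 2
    diam = 2.0 * np.sqrt(area / np.pi)
    below = diam < min_caliber
    s = straight_lumen.arc_length
    spans = []
    i = 0
    while i < len(below):
        if below[i]:
            j = i
            while j + 1 < len(below) and below[j + 1]:
                j += 1
            lo, hi = float(s[i]), float(s[j])
            exempt = any(w0 <= lo and hi <= w1 for (w0, w1) in stenosis_windows)
            if not exempt:
                spans.append((lo, hi))
            i = j + 1
        else:
            i += 1
    return spans
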