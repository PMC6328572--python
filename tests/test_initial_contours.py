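import numpy as np
import pytest
from scipy.ndimage import distance_transform_edt, generate_binary_structure, label

from coroseg.grid import BinaryMask, SeedPoint, Volume
from coroseg.initial_contours import (OuterInitParams,
                                      RegionGrowParams, SeedRejectionError,
                                      default_vesselness_window, geodesic_distance,
                                      lumen_initial_contour, outer_initial_contour,
                                      region_grow)
from coroseg.phantom import PhantomSpec, confounder_bright_sheet, line_curve, make_phantom
from coroseg.vesselness import frangi_vesselness

SP = (0.4, 0.4, 0.4)


def _edt_oracle(lumen, volume, distance=5.5, fat_threshold=0.0):
    """Independent restricted-dilation oracle: Euclidean distance transform
    thresholded within the 6-connected reachable part of the non-fat domain."""
    dom = (volume.data >= fat_threshold) | lumen.data
    lab, _ = label(dom, structure=generate_binary_structure(3, 1))
    keep = np.unique(lab[lumen.data])
    reach = np.isin(lab, keep[keep > 0])
    edt = distance_transform_edt(~lumen.data, sampling=volume.grid.spacing)
    return ((edt <= distance) & reach) | lumen.data


class TestRegionGrow:
    def test_uniform_volume_fills(self):
        vol = Volume.from_array(np.full((12, 12, 12), 300.0), (1, 1, 1))
        out = region_grow(vol, [SeedPoint((5, 5, 5))], RegionGrowParams(200, 400))
        assert out.count == 12 ** 3

    def test_only_seeded_blob_kept(self):
        data = np.zeros((20, 20, 20))
        data[2:6, 2:6, 2:6] = 300.0
        data[12:16, 12:16, 12:16] = 300.0
        vol = Volume.from_array(data, (1, 1, 1))
        out = region_grow(vol, [SeedPoint((3, 3, 3))], RegionGrowParams(200, 400))
        assert out.count == 4 ** 3
        assert out.data[3, 3, 3] and not out.data[13, 13, 13]

    def test_phantom_lumen_within_one_voxel_shell(self, bare_tube):
        seed = bare_tube.seed_near_start(2.0)
        out = region_grow(bare_tube.volume, [seed], RegionGrowParams(200, 600))
        truth = bare_tube.lumen_mask.data
        from scipy.ndimage import binary_dilation
        shell_out = binary_dilation(truth, generate_binary_structure(3, 3))
        shell_in = ~binary_dilation(~truth, generate_binary_structure(3, 3))
        assert not np.any(out.data & ~shell_out)   # no voxel beyond truth+1
        assert not np.any(shell_in & ~out.data)    # all of truth-eroded-1 present

    def test_seed_out_of_range_rejected(self):
        vol = Volume.from_array(np.zeros((10, 10, 10)), (1, 1, 1))
        with pytest.raises(SeedRejectionError, match="outside"):
            region_grow(vol, [SeedPoint((5, 5, 5))], RegionGrowParams(200, 400))

    def test_connectivity_validation(self):
        with pytest.raises(ValueError):
            RegionGrowParams(0, 1, connectivity=18)
        with pytest.raises(ValueError):
            RegionGrowParams(5, 1)


class TestLumenInitial:
    def test_intersection_is_subset_of_both(self, straight_tube):
        tr = straight_tube
        ves = frangi_vesselness(tr.volume)
        win = default_vesselness_window(ves)
        seeds = [tr.seed_near_start(2.0)]
        hu = region_grow(tr.volume, seeds, RegionGrowParams(175, 800))
        vg = region_grow(ves, seeds, win)
        s1 = lumen_initial_contour(tr.volume, ves, seeds, RegionGrowParams(175, 800), win)
        assert not np.any(s1.data & ~hu.data)
        assert not np.any(s1.data & ~vg.data)

    def test_bright_sheet_rejected_from_s1(self, straight_tube):
        """With an inclusive vesselness window (the kind needed to keep faint
        distal segments), the vesselness-only growth reaches the sheet; the
        HU intersection rejects every sheet voxel."""
        tr = confounder_bright_sheet(straight_tube, offset=1.5, hu=400.0)
        ves = frangi_vesselness(tr.volume)
        win = RegionGrowParams(0.03, float("inf"))
        seeds = [tr.seed_near_start(2.0)]
        vg = region_grow(ves, seeds, win)
        s1 = lumen_initial_contour(tr.volume, ves, seeds, RegionGrowParams(175, 800), win)
        assert int((vg.data & tr.sheet_mask.data).sum()) > 0
        assert int((s1.data & tr.sheet_mask.data).sum()) == 0

    def test_attached_bright_reservoir_suppressed(self):
        """A large blood-pool blob attached to the vessel (aorta surrogate) is
        HU-connected but not tube-like, so the intersection drops it."""
        curve = line_curve((9.4, 9.4, 8.0), (9.4, 9.4, 44.0))
        tr = make_phantom(PhantomSpec(curve=curve, fat_sheath=False), (48, 48, 130), SP)
        vol = tr.volume.data.copy()
        ball = np.zeros_like(vol, bool)
        idx = np.indices(vol.shape).transpose(1, 2, 3, 0)
        c = np.array([23.5, 23.5, 12.0])
        ball[(np.linalg.norm((idx - c) * 0.4, axis=-1) <= 6.0)] = True
        vol[ball] = 400.0
        vol2 = Volume(vol, tr.volume.grid)
        ves = frangi_vesselness(vol2)
        win = default_vesselness_window(ves)
        seeds = [tr.seed_near_end(2.0)]
        s1 = lumen_initial_contour(vol2, ves, seeds, RegionGrowParams(175, 800), win)
        core = ball & (np.linalg.norm((idx - c) * 0.4, axis=-1) <= 4.0)
        assert int((s1.data & core).sum()) == 0



class TestOuterInitial:
    def test_fat_free_voxel_identical_to_edt_oracle(self, bare_tube):
        out = outer_initial_contour(bare_tube.lumen_mask, bare_tube.volume,
                                    OuterInitParams())
        oracle = _edt_oracle(bare_tube.lumen_mask, bare_tube.volume)
        assert np.array_equal(out.data, oracle)

    def test_fat_free_volume_matches_analytic(self):
        curve = line_curve((12.6, 12.6, 0.0), (12.6, 12.6, 59.6))
        tr = make_phantom(PhantomSpec(curve=curve, fat_sheath=False), (64, 64, 150), SP)
        out = outer_initial_contour(tr.lumen_mask, tr.volume, OuterInitParams())
        analytic = np.pi * 7.0 ** 2 * 59.6  # lumen 1.5 mm + 5.5 mm dilation
        assert out.volume_mm3 == pytest.approx(analytic, rel=0.05)

    def test_fat_ring_blocks_dilation(self):
        curve = line_curve((12.6, 12.6, 0.0), (12.6, 12.6, 59.6))
        spec = PhantomSpec(curve=curve, fat_sheath=True, fat_gap=0.75,
                           fat_thickness=0.4, partial_volume=False)
        tr = make_phantom(spec, (64, 64, 150), SP)  # fat ring at 3.0-3.4 mm
        out = outer_initial_contour(tr.lumen_mask, tr.volume, OuterInitParams())
        oracle = _edt_oracle(tr.lumen_mask, tr.volume)
        assert np.array_equal(out.data, oracle)
        idx = np.argwhere(out.data)
        r = np.linalg.norm(idx[:, :2] * 0.4 - 12.6, axis=1)
        assert r.max() < 3.0 + 1e-6  # nothing beyond the ring

    def test_contains_lumen_and_monotone_in_distance(self, bare_tube):
        small = outer_initial_contour(bare_tube.lumen_mask, bare_tube.volume,
                                      OuterInitParams(dilation_distance=2.0))
        big = outer_initial_contour(bare_tube.lumen_mask, bare_tube.volume,
                                    OuterInitParams(dilation_distance=4.0))
        assert not np.any(bare_tube.lumen_mask.data & ~small.data)
        assert not np.any(small.data & ~big.data)

    def test_empty_lumen_rejected(self, bare_tube):
        empty = BinaryMask.from_array(np.zeros(bare_tube.volume.grid.shape, bool), SP)
        with pytest.raises(ValueError):
            outer_initial_contour(empty, bare_tube.volume)

    def test_geodesic_distance_matches_dijkstra_on_small_grid(self):
        """Voxel-exact agreement with an independent Dijkstra at matched
        discretization (26-neighborhood, Euclidean edge lengths, chamfer
        slack), including around a barrier."""
        import networkx as nx

        shape = (9, 9, 9)
        domain = np.ones(shape, bool)
        domain[4, :, :] = False          # wall...
        domain[4, 4, 4] = True           # ...with a one-voxel gap
        sources = np.zeros(shape, bool)
        sources[1, 4, 4] = True
        sp = (0.5, 0.5, 0.5)
        dist = geodesic_distance(domain, sources, sp)

        g = nx.Graph()
        offs = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
                if (i, j, k) != (0, 0, 0)]
        vox = np.argwhere(domain | sources)
        vset = {tuple(v) for v in vox}
        for v in vset:
            for o in offs:
                w = tuple(np.add(v, o))
                if w in vset:
                    g.add_edge(v, w, weight=np.linalg.norm(np.array(o) * sp))
        ref = nx.single_source_dijkstra_path_length(g, (1, 4, 4))
        from coroseg.initial_contours import _chamfer_slack
        slack = _chamfer_slack(sp, 26)
        edt = distance_transform_edt(~sources, sampling=sp)
        for v in vset:
            expect = max(edt[v], ref[v] / slack) if v in ref else np.inf
            assert dist[v] == pytest.approx(expect, abs=1e-9)
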