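import numpy as np
import pytest
from scipy.ndimage import binary_erosion, distance_transform_edt, generate_binary_structure

from coroseg.grid import BinaryMask, Volume
from coroseg.levelset import (FeatureImage, LevelSetParams, WallSegmentation,
                              compute_feature_image, evolve_level_set,
                              gradient_magnitude, segment_boundary, segment_wall)
from coroseg.phantom import PhantomSpec, line_curve, make_phantom

SP = (0.4, 0.4, 0.4)


@pytest.fixture(scope="module")
def sharp_tube():
    """Sharp-edged cylinder (no partial-volume rendering, no fat)."""
    curve = line_curve((9.4, 9.4, 6.0), (9.4, 9.4, 46.0))
    return make_phantom(PhantomSpec(curve=curve, fat_sheath=False,
                                    partial_volume=False), (48, 48, 130), SP)


class TestFeatureImage:
    def test_constant_volume_full_speed(self):
        vol = Volume.from_array(np.full((16, 16, 16), 120.0), (1, 1, 1))
        feat = compute_feature_image(vol, LevelSetParams(sigmoid_beta=50.0))
        assert np.all(feat.data > 1.0 - 1e-6)

    def test_step_edge_minimum_at_edge_plane(self):
        data = np.zeros((16, 16, 40))
        data[:, :, 20:] = 400.0
        vol = Volume.from_array(data, SP)
        p = LevelSetParams(gradient_sigma=0.4)
        feat = compute_feature_image(vol, p)
        profile = feat.data[8, 8, :]
        k_min = int(np.argmin(profile))
        assert k_min in (19, 20)
        assert profile[k_min] < 0.1
        # closed-form check: peak gradient of a Gaussian-smoothed step of
        # height h is h / (sigma * sqrt(2*pi))
        g = gradient_magnitude(vol, 0.4)
        expected_peak = 400.0 / (0.4 * np.sqrt(2 * np.pi))
        assert g[8, 8, 19:21].max() == pytest.approx(expected_peak, rel=0.15)

    def test_monotone_nonincreasing_in_gradient(self, straight_tube):
        p = LevelSetParams(gradient_sigma=0.4, sigmoid_beta=150.0)
        feat = compute_feature_image(straight_tube.volume, p)
        g = feat.gmag.ravel()
        f = feat.data.ravel()
        order = np.argsort(g)
        assert np.all(np.diff(f[order]) <= 1e-12)

    def test_range(self, straight_tube):
        feat = compute_feature_image(straight_tube.volume, LevelSetParams())
        assert feat.data.min() >= 0.0 and feat.data.max() <= 1.0


class TestEvolveLevelSet:
    def test_zero_feature_returns_initial_unchanged(self):
        init = np.zeros((20, 20, 20), bool)
        init[8:12, 8:12, 8:12] = True
        mask = BinaryMask.from_array(init, (1, 1, 1))
        feat = FeatureImage(data=np.zeros((20, 20, 20)),
                            grid=mask.grid, beta=1.0, alpha=0.5)
        out = evolve_level_set(mask, feat, LevelSetParams())
        assert np.array_equal(out.data, init)
        assert out.converged and out.iterations == 0  # zero-speed short-circuit

    def test_empty_initial_rejected(self):
        mask = BinaryMask.from_array(np.zeros((8, 8, 8), bool), (1, 1, 1))
        feat = FeatureImage(data=np.ones((8, 8, 8)), grid=mask.grid, beta=1, alpha=1)
        with pytest.raises(ValueError):
            evolve_level_set(mask, feat)

    def test_curvature_only_sphere_shrinks_monotonically(self):
        """With propagation and advection off and speed identically 1, the
        curvature term alone drives mean-curvature-like shrinkage of a small
        sphere (curvature above the discrete scheme's resolution)."""
        n = 24
        idx = np.indices((n, n, n)).transpose(1, 2, 3, 0)
        r = np.linalg.norm(idx - 12, axis=-1)
        mask = BinaryMask.from_array(r <= 5, (1, 1, 1))
        feat = FeatureImage(data=np.ones((n, n, n)), grid=mask.grid, beta=1, alpha=1)
        p = LevelSetParams(propagation_weight=0.0, advection_weight=0.0,
                           curvature_weight=1.0, max_iterations=3,
                           rms_convergence=1e-12)
        vols = [mask.count]
        cur = mask
        for _ in range(5):
            cur = evolve_level_set(cur, feat, p)
            vols.append(cur.count)
        assert all(a >= b for a, b in zip(vols, vols[1:]))
        assert vols[-1] < vols[0]

    def test_eroded_truth_expands_to_boundary(self, sharp_tube):
        """Outward evolution from a 2-voxel-eroded truth mask recovers the
        sharp lumen surface to within one voxel (chessboard Hausdorff)."""
        from scipy.ndimage import distance_transform_cdt
        truth = sharp_tube.lumen_mask
        st = generate_binary_structure(3, 1)
        init = BinaryMask(binary_erosion(truth.data, st, 2), truth.grid)
        p = LevelSetParams(gradient_sigma=0.4, max_iterations=100)
        feat = compute_feature_image(sharp_tube.volume, p, around=init)
        out = evolve_level_set(init, feat, p)
        d_truth = distance_transform_cdt(~truth.data, metric="chessboard")
        d_out = distance_transform_cdt(~out.data, metric="chessboard")
        interior = np.zeros_like(truth.data)
        interior[:, :, 20:-20] = True  # in-plane check away from the tube caps
        assert d_truth[out.data & interior].max() <= 1
        assert d_out[truth.data & interior].max() <= 1

    def test_truth_init_is_exact_fixed_point_without_side_forces(self, sharp_tube):
        """From the exact truth mask, with propagation gated off at the edge
        and attraction/curvature disabled, the front is strictly stationary."""
        truth = sharp_tube.lumen_mask
        p = LevelSetParams(gradient_sigma=0.4, curvature_weight=0.0,
                           advection_weight=0.0, max_iterations=100)
        feat = compute_feature_image(sharp_tube.volume, p, around=truth)
        out = evolve_level_set(truth, feat, p)
        assert np.array_equal(out.data, truth.data)

    def test_truth_init_is_near_fixed_point(self, straight_tube):
        """Full default evolution from the exact truth recovers it to DICE
        >= 99% (boundary voxels may be re-decided by the edge attraction)."""
        truth = straight_tube.lumen_mask
        p = LevelSetParams(gradient_sigma=0.4, max_iterations=150)
        out = segment_boundary(straight_tube.volume, truth, p, supersample=3)
        dice = 200.0 * (out.data & truth.data).sum() / (out.count + truth.count)
        assert dice >= 99.0

    def test_supersampled_refinement_improves_on_native(self, straight_tube):
        truth = straight_tube.lumen_mask
        st = generate_binary_structure(3, 1)
        init = BinaryMask(binary_erosion(truth.data, st, 2), truth.grid)
        p = LevelSetParams(gradient_sigma=0.4, max_iterations=100)
        fine = segment_boundary(straight_tube.volume, init, p, supersample=3)
        dice = 200.0 * (fine.data & truth.data).sum() / (fine.count + truth.count)
        assert dice >= 97.0


class TestSegmentWall:
    def test_lumen_equals_vessel_gives_empty_wall(self):
        m = BinaryMask.from_array(np.ones((8, 8, 8), bool), (1, 1, 1))
        ws = segment_wall(m, m)
        assert ws.wall.count == 0

    def test_annulus_volume(self):
        n = 64
        idx = np.indices((n, n, 40)).transpose(1, 2, 3, 0).astype(float)
        r = np.linalg.norm(idx[..., :2] * 0.4 - 12.6, axis=-1)
        lumen = BinaryMask.from_array(r <= 1.5, SP)
        vessel = BinaryMask.from_array(r <= 2.5, SP)
        ws = segment_wall(lumen, vessel)
        analytic = np.pi * (2.5 ** 2 - 1.5 ** 2) * 40 * 0.4
        assert ws.wall.volume_mm3 == pytest.approx(analytic, rel=0.05)

    def test_disjoint_inputs_enforced_to_containment(self):
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a[2:4, 2:4, 2:4] = True
        b[6:8, 6:8, 6:8] = True
        ws = segment_wall(BinaryMask.from_array(a, (1, 1, 1)),
                          BinaryMask.from_array(b, (1, 1, 1)))
        assert not np.any(ws.lumen.data & ~ws.vessel.data)
        assert np.array_equal(ws.wall.data, ws.vessel.data & ~ws.lumen.data)

    def test_invariants_validated(self):
        g = (1, 1, 1)
        lum = BinaryMask.from_array(np.ones((8, 8, 8), bool), g)
        ves = BinaryMask.from_array(np.zeros((8, 8, 8), bool), g)
        with pytest.raises(ValueError):
            WallSegmentation(lumen=lum, vessel=ves, wall=ves)
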