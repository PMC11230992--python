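"""Global/local artifact scoring, overlays and tilt recommendation."""

import numpy as np
import pytest

from cbctmaa.geometry import DetectorSpec, ScanProtocol, Trajectory, enumerate_tilt_grid, make_circular_trajectory
from cbctmaa.maa import (
    TaskROI,
    WelfordAccumulator,
    _bilinear_sample,
    global_score,
    recommend_tilt,
    render_overlay,
    score_curve,
    voxel_impact_map,
)
from cbctmaa.phantoms import MetalMask, ScrewSpec, VoxelGrid, make_screw_mask, make_wedge_mask
from cbctmaa.projector import _ray_matrix, project_trajectory
from cbctmaa.spectral import Spectrum, default_spectrum, material_attenuation, shift_stack, single_energy_spectrum


@pytest.fixture(scope="module")
def tiny_protocol():
    det = DetectorSpec(n_u=64, n_v=64, pixel_size_u=2.0, pixel_size_v=2.0)
    return ScanProtocol(n_views=40, detector=det)


class TestWelford:
    def test_matches_two_pass_variance(self):
        rng = np.random.default_rng(5)
        data = rng.normal(3.0, 2.0, size=(200, 100))
        acc = WelfordAccumulator(100)
        for row in data:
            acc.update(row)
        ref = np.var(data, axis=0)
        np.testing.assert_allclose(acc.variance(), ref, rtol=1e-10)
        np.testing.assert_allclose(acc.mean, data.mean(axis=0), rtol=1e-12)

    def test_subset_updates_track_per_element_streams(self):
        rng = np.random.default_rng(6)
        n = 50
        streams = [[] for _ in range(n)]
        acc = WelfordAccumulator(n)
        for _ in range(80):
            mask = rng.random(n) < 0.7
            vals = rng.normal(size=int(mask.sum()))
            acc.update(vals, mask)
            for i, v in zip(np.flatnonzero(mask), vals):
                streams[i].append(v)
        for i in range(n):
            if streams[i]:
                assert acc.variance()[i] == pytest.approx(np.var(streams[i]), rel=1e-10, abs=1e-12)

    def test_single_sample_variance_is_zero(self):
        acc = WelfordAccumulator(3)
        acc.update(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_array_equal(acc.variance(), 0.0)


class TestGlobalScore:
    def test_centered_sphere_scores_far_below_off_center_rod(self, tiny_protocol):
        sphere_grid = VoxelGrid(shape=(64, 64, 64), voxel_size=0.5)
        X, Y, Z = sphere_grid.meshgrid()
        sphere = MetalMask(sphere_grid, (X**2 + Y**2 + Z**2 <= 12.0**2).astype(np.uint8))
        rod_grid = VoxelGrid(shape=(64, 64, 64), voxel_size=0.75)
        rod = make_screw_mask(rod_grid, ScrewSpec(head=(-20, 14, 8), tip=(20, 14, 8), diameter=8.0))
        traj = tiny_protocol.trajectory(0.0)
        s_sphere = global_score(sphere, traj)
        s_rod = global_score(rod, traj)
        assert s_sphere < 1e-3 * s_rod

    def test_empty_mask_rejected(self, tiny_protocol):
        grid = VoxelGrid(shape=(16, 16, 16), voxel_size=2.0)
        empty = MetalMask(grid, np.zeros(grid.shape, dtype=np.uint8))
        with pytest.raises(ValueError, match="empty"):
            global_score(empty, tiny_protocol.trajectory(0.0))

    def test_single_view_variance_is_zero(self, tiny_protocol):
        grid = VoxelGrid(shape=(32, 32, 32), voxel_size=1.5)
        mask = make_screw_mask(grid, ScrewSpec(head=(-10, 0, 0), tip=(10, 0, 0)))
        two = tiny_protocol.trajectory(0.0)
        single = Trajectory(views=two.views[:1], arc_degrees=0.0, tilt=0.0)
        assert global_score(mask, single) == 0.0


class TestScoreCurve:
    @pytest.fixture(scope="class")
    def rod_curve(self, tiny_protocol):
        grid = VoxelGrid(shape=(48, 48, 48), voxel_size=1.0)
        mask = make_screw_mask(grid, ScrewSpec(head=(-14, 0, 0), tip=(14, 0, 0), diameter=5.0))
        return score_curve(mask, enumerate_tilt_grid(-30, 30, 5), tiny_protocol)

    def test_thirteen_scores_on_default_grid(self, rod_curve):
        assert len(rod_curve.raw) == 13

    def test_normalized_attains_zero_and_one(self, rod_curve):
        assert rod_curve.normalized.min() == 0.0
        assert rod_curve.normalized.max() == 1.0

    def test_symmetric_mask_gives_symmetric_curve(self, rod_curve):
        # rod along x at z=0 is mirror-symmetric about the orbital plane
        asym = np.abs(rod_curve.normalized - rod_curve.normalized[::-1]).max()
        assert asym < 0.05

    def test_degenerate_scores_flagged(self, tiny_protocol):
        grid = VoxelGrid(shape=(32, 32, 32), voxel_size=1.5)
        mask = make_screw_mask(grid, ScrewSpec(head=(-10, 0, 0), tip=(10, 0, 0)))
        curve = score_curve(
            mask, enumerate_tilt_grid(-10, 10, 10), tiny_protocol, spectrum=single_energy_spectrum()
        )
        assert curve.degenerate
        np.testing.assert_array_equal(curve.normalized, 0.0)


class TestVoxelImpactMap:
    @pytest.fixture(scope="class")
    def screw_setup(self, tiny_protocol):
        grid = VoxelGrid(shape=(48, 48, 48), voxel_size=1.0)
        mask = make_screw_mask(grid, ScrewSpec(head=(-14, 4, -6), tip=(12, -6, 8), diameter=5.0))
        traj = tiny_protocol.trajectory(5.0)
        return grid, mask, traj

    def test_single_energy_spectrum_gives_zero_impact(self, screw_setup):
        _, mask, traj = screw_setup
        imp = voxel_impact_map(mask, traj, spectrum=single_energy_spectrum())
        np.testing.assert_array_equal(imp.values, 0.0)

    def test_support_never_exceeds_mask_support(self, screw_setup):
        _, mask, traj = screw_setup
        imp = voxel_impact_map(mask, traj)
        assert (imp.values[mask.values == 0] == 0).all()
        assert (imp.values >= 0).all()

    def test_welford_equals_two_pass_on_projected_samples(self, screw_setup):
        _, mask, traj = screw_setup
        spectrum = default_spectrum()
        ti = material_attenuation("titanium")
        shifts = shift_stack(project_trajectory(mask, traj), spectrum, ti)
        imp = voxel_impact_map(mask, traj, shifts=shifts)
        det = traj.detector
        rng = np.random.default_rng(2)
        idx = mask.metal_indices()
        for row in idx[rng.choice(len(idx), 100, replace=False)]:
            center = mask.grid.voxel_centers(row[None, :])[0]
            samples = []
            for i, view in enumerate(traj):
                hom = view.P @ np.append(center, 1.0)
                u, v = hom[0] / hom[2], hom[1] / hom[2]
                if 0 <= u <= det.n_u - 1 and 0 <= v <= det.n_v - 1:
                    samples.append(_bilinear_sample(shifts[i], np.array([u]), np.array([v]))[0])
            two_pass = np.var(samples)
            assert imp.values[tuple(row)] == pytest.approx(two_pass, rel=1e-10, abs=1e-15)

    def test_mu_scaling_preserves_impact_ordering(self, tiny_protocol):
        # small wedge: thickness ramp; scaling mu(E) by a constant changes
        # the shift nonlinearly but must keep the per-voxel impact ranking
        from scipy.stats import spearmanr

        grid = VoxelGrid(shape=(32, 32, 32), voxel_size=4.8)
        wedge = make_wedge_mask(grid)
        traj = ScanProtocol(n_views=40).trajectory(0.0)
        ti = material_attenuation("titanium")
        from cbctmaa.spectral import MaterialAttenuation

        ti_scaled = MaterialAttenuation("ti_x", ti.energies_kev, 1.5 * ti.mu_per_mm)
        imp1 = voxel_impact_map(wedge, traj, material=ti)
        imp2 = voxel_impact_map(wedge, traj, material=ti_scaled)
        sel = wedge.values > 0
        rho = spearmanr(imp1.values[sel], imp2.values[sel]).statistic
        assert rho > 0.95


class TestOverlay:
    def _scout(self):
        det = DetectorSpec(n_u=32, n_v=32, pixel_size_u=4.0, pixel_size_v=4.0)
        return make_circular_trajectory(0.0, n_views=3, detector=det)[1]

    def test_zero_impact_is_fully_transparent(self):
        from cbctmaa.maa import VoxelImpactMap, overlay_rgba

        grid = VoxelGrid(shape=(16, 16, 16), voxel_size=2.0)
        imp = VoxelImpactMap(grid, np.zeros(grid.shape), 0.0)
        ov = render_overlay(imp, self._scout(), c_crit=1.0)
        assert np.all(ov.color == 0)
        assert np.all(overlay_rgba(ov)[..., 3] == 0)

    def test_single_voxel_support_matches_ray_box_oracle(self):
        from cbctmaa.maa import VoxelImpactMap

        grid = VoxelGrid(shape=(16, 16, 16), voxel_size=2.0)
        vals = np.zeros(grid.shape)
        vals[9, 6, 8] = 2.5
        imp = VoxelImpactMap(grid, vals, 0.0)
        scout = self._scout()
        ov = render_overlay(imp, scout, c_crit=1.0)
        # independent slab-test oracle for the voxel's box
        center = grid.voxel_centers(np.array([[9, 6, 8]]))[0]
        lo_box = center - grid.voxel_size / 2
        hi_box = center + grid.voxel_size / 2
        rm = _ray_matrix(scout)
        src = scout.source_position
        hits = np.zeros((32, 32), dtype=bool)
        for u in range(32):
            for v in range(32):
                d = rm @ np.array([u, v, 1.0])
                with np.errstate(divide="ignore"):
                    t0 = (lo_box - src) / d
                    t1 = (hi_box - src) / d
                tmin = np.minimum(t0, t1).max()
                tmax = np.maximum(t0, t1).min()
                hits[u, v] = tmax > tmin + 1e-12
        np.testing.assert_array_equal(ov.values > 0, hits)
        assert ov.values.max() == pytest.approx(2.5)

    def test_values_at_or_above_c_crit_saturate(self):
        from cbctmaa.maa import VoxelImpactMap

        grid = VoxelGrid(shape=(8, 8, 8), voxel_size=4.0)
        imp = VoxelImpactMap(grid, np.full(grid.shape, 5.0), 0.0)
        ov = render_overlay(imp, self._scout(), c_crit=2.0)
        assert ov.color.max() == 1.0
        assert np.all(ov.color[ov.values > 0] == 1.0)

    def test_non_positive_c_crit_rejected(self):
        from cbctmaa.maa import VoxelImpactMap

        grid = VoxelGrid(shape=(8, 8, 8), voxel_size=4.0)
        imp = VoxelImpactMap(grid, np.zeros(grid.shape), 0.0)
        with pytest.raises(ValueError):
            render_overlay(imp, self._scout(), c_crit=0.0)


class TestRecommendTilt:
    def test_single_tilt_grid_returns_it(self, tiny_protocol):
        grid = VoxelGrid(shape=(32, 32, 32), voxel_size=1.5)
        mask = make_screw_mask(grid, ScrewSpec(head=(-10, 0, 0), tip=(10, 0, 0)))
        roi = TaskROI(grid, mask.values)
        best, means = recommend_tilt(mask, enumerate_tilt_grid(5, 5, 1), roi, tiny_protocol)
        assert best == 5.0
        assert len(means) == 1

    def test_mirrored_phantoms_recommend_mirrored_tilts(self, tiny_protocol):
        grid = VoxelGrid(shape=(48, 48, 48), voxel_size=1.0)
        a = np.deg2rad(15.0)
        half = np.array([0.0, np.cos(a), np.sin(a)]) * 12.0
        up = make_screw_mask(grid, ScrewSpec(head=tuple(-half), tip=tuple(half), diameter=5.0))
        dn = make_screw_mask(
            grid, ScrewSpec(head=tuple(-half * [1, 1, -1]), tip=tuple(half * [1, 1, -1]), diameter=5.0)
        )
        tg = enumerate_tilt_grid(-20, 20, 10)
        best_up, _ = recommend_tilt(up, tg, TaskROI(grid, up.values), tiny_protocol)
        best_dn, _ = recommend_tilt(dn, tg, TaskROI(grid, dn.values), tiny_protocol)
        assert abs(best_up) == abs(best_dn)
        assert best_up == -best_dn or best_up == best_dn == 0.0

    def test_roi_disjoint_from_metal_rejected(self, tiny_protocol):
        grid = VoxelGrid(shape=(32, 32, 32), voxel_size=1.5)
        mask = make_screw_mask(grid, ScrewSpec(head=(-10, 0, 0), tip=(10, 0, 0)))
        far = np.zeros(grid.shape, dtype=bool)
        far[0, 0, 0] = True
        with pytest.raises(ValueError, match="ROI"):
            recommend_tilt(mask, enumerate_tilt_grid(0, 0, 1), TaskROI(grid, far), tiny_protocol)


def test_task_roi_validation():
    grid = VoxelGrid(shape=(8, 8, 8), voxel_size=1.0)
    with pytest.raises(ValueError, match="non-empty"):
        TaskROI(grid, np.zeros(grid.shape, dtype=bool))
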