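"""OSEM reconstruction and post-processing."""

import numpy as np
import pytest

from slacspect import phantom as ph
from slacspect.forward_model import AcquisitionGeometry, ProjectionSet, get_projector
from slacspect.recon import (
    ReconConfig,
    butterworth_filter,
    extract_roi,
    osem,
    poisson_loglik,
    reconstruct_initial_estimates,
    reorient_short_axis,
    short_axis_point,
)


@pytest.fixture(scope="module")
def small_recon_setup():
    """32^3 phantom-like disk with matched noiseless projections."""
    # no CDR: the pure attenuated projector inverts quickly, which keeps the
    # matched-model self-consistency checks sharp
    geom = AcquisitionGeometry(
        n_angles=48, n_bins=(32, 32), cdr_sigma_cm=0.0, cdr_slope=0.0
    )
    n = 32
    x, y = np.meshgrid(np.arange(n) - 15.5, np.arange(n) - 15.5, indexing="ij")
    disk = (x**2 + y**2 <= 100).astype(np.float32)
    act = np.repeat(disk[:, :, None], n, axis=2)
    act[:, :, :8] = 0
    act[:, :, 24:] = 0
    mu = (act > 0).astype(np.float32) * 0.15
    proj = get_projector(geom, np.float32)
    plan = proj.attenuation_plan(mu)
    data = proj.forward(act, att_plan=plan)
    return geom, act, mu, data


class TestOSEM:
    def test_zero_projections_fixed_point(self, small_recon_setup):
        geom, _, _, _ = small_recon_setup
        zero = np.zeros((geom.n_angles, 32, 32), dtype=np.float32)
        rec = osem(zero, geom, ReconConfig(n_subsets=4, n_iterations=2))
        assert rec.sum() == 0.0

    def test_nonnegative_output(self, small_recon_setup):
        geom, _, mu, data = small_recon_setup
        noisy = np.random.default_rng(0).poisson(data * 50).astype(np.float32)
        rec = osem(noisy, geom, ReconConfig(n_subsets=4, n_iterations=3,
                                            use_attenuation=True, mu_map=mu))
        assert np.all(rec >= 0)

    def test_mlem_loglikelihood_nondecreasing_over_50_iterations(
        self, small_recon_setup
    ):
        geom, _, mu, data = small_recon_setup
        proj = get_projector(geom, np.float32)
        plan = proj.attenuation_plan(mu)
        liks = []
        for it in (1, 10, 25, 50):
            rec = osem(data, geom, ReconConfig(
                n_subsets=1, n_iterations=it, use_attenuation=True, mu_map=mu
            ))
            liks.append(poisson_loglik(data, proj.forward(rec, att_plan=plan)))
        assert all(b >= a - 1e-3 * abs(a) for a, b in zip(liks, liks[1:]))

    def test_uniform_disk_recovered_within_5_percent(self, small_recon_setup):
        geom, act, mu, data = small_recon_setup
        rec = osem(data, geom, ReconConfig(
            n_subsets=1, n_iterations=100, use_attenuation=True, mu_map=mu
        ))
        # interior: stay 3.5 voxels inside the rim; the rim's partial-volume
        # voxels (and their reconstruction penumbra) cannot be represented
        # exactly on the grid
        n = 32
        x, y = np.meshgrid(np.arange(n) - 15.5, np.arange(n) - 15.5,
                           indexing="ij")
        interior = (act > 0) & np.repeat(
            ((x**2 + y**2) <= 6.5**2)[:, :, None], n, axis=2
        )
        rel_err = np.abs(rec[interior] - act[interior]) / act[interior]
        assert rel_err.max() <= 0.05

    def test_subset_count_must_divide_angles(self, small_recon_setup):
        geom, _, _, data = small_recon_setup
        with pytest.raises(ValueError):
            osem(data, geom, ReconConfig(n_subsets=7, n_iterations=1))

    def test_attenuation_requires_mu_map(self):
        with pytest.raises(ValueError):
            ReconConfig(use_attenuation=True)


@pytest.fixture(scope="module")
def pset(small_recon_setup):
    geom, act, mu, data = small_recon_setup
    return ProjectionSet(geom, data.astype(np.float64),
                         (data * 0.3).astype(np.float64))


class TestInitialEstimates:

    def test_output_shapes_match_grid(self, pset):
        s_rec, pp_rec = reconstruct_initial_estimates(
            pset, ReconConfig(n_subsets=4, n_iterations=2)
        )
        assert s_rec.shape == (32, 32, 32)
        assert pp_rec.shape == (32, 32, 32)

    def test_unit_mean_normalization_over_support(self, pset):
        s_rec, pp_rec = reconstruct_initial_estimates(
            pset, ReconConfig(n_subsets=4, n_iterations=2)
        )
        for rec in (s_rec, pp_rec):
            support = rec > 1e-6 * rec.max()
            assert rec[support].mean() == pytest.approx(1.0, rel=1e-5)

    def test_zero_scatter_counts_give_zero_reconstruction(self, small_recon_setup):
        geom, _, _, data = small_recon_setup
        pset = ProjectionSet(geom, data.astype(np.float64),
                             np.zeros_like(data, dtype=np.float64))
        s_rec, _ = reconstruct_initial_estimates(
            pset, ReconConfig(n_subsets=4, n_iterations=2)
        )
        assert s_rec.sum() == 0.0

    def test_missing_scatter_window_rejected(self, small_recon_setup):
        geom, _, _, data = small_recon_setup
        pset = ProjectionSet(geom, data.astype(np.float64), None)
        with pytest.raises(ValueError):
            reconstruct_initial_estimates(pset)

    def test_scatter_recon_correlates_with_attenuation_map(self, default_phantom):
        # physics premise: the scatter window carries attenuation contrast
        from slacspect.forward_model import forward_project, simulate_scatter

        geom = AcquisitionGeometry(n_angles=30)
        p = default_phantom
        primary = forward_project(p.activity, p.mu, geom)
        scat = simulate_scatter(p.activity, p.mu, geom, primary=primary)
        pset = ProjectionSet(geom, primary.astype(np.float64),
                             scat.astype(np.float64))
        s_rec, _ = reconstruct_initial_estimates(
            pset, ReconConfig(n_subsets=6, n_iterations=5)
        )
        body = (p.labels > 0) & (p.labels != ph.TABLE)
        r = np.corrcoef(s_rec[body], p.mu[body])[0, 1]
        assert r >= 0.5


class TestCTACvsNACPhysics:
    def test_nac_suppresses_deep_regions_relative_to_ctac(self):
        # uniform-activity cylinder: without attenuation compensation the
        # deepest region reconstructs darker than with compensation
        geom = AcquisitionGeometry(n_angles=24, n_bins=(32, 32))
        n = 32
        x, y = np.meshgrid(np.arange(n) - 15.5, np.arange(n) - 15.5,
                           indexing="ij")
        body = (x**2 + y**2 <= 144)
        act = np.repeat(body[:, :, None], n, axis=2).astype(np.float32)
        mu = act * np.float32(0.15)
        data = get_projector(geom, np.float32).forward(
            act, att_plan=get_projector(geom, np.float32).attenuation_plan(mu)
        )
        ctac = osem(data, geom, ReconConfig(n_subsets=4, n_iterations=5,
                                            use_attenuation=True, mu_map=mu))
        nac = osem(data, geom, ReconConfig(n_subsets=4, n_iterations=5))
        deep = np.zeros_like(act, dtype=bool)
        deep[13:19, 13:19, 12:20] = True  # center of the cylinder
        shallow = (act > 0) & ~deep
        ratio_ctac = ctac[deep].mean() / ctac[shallow].mean()
        ratio_nac = nac[deep].mean() / nac[shallow].mean()
        assert ratio_nac < ratio_ctac


class TestButterworth:
    def test_constant_volume_unchanged(self):
        vol = np.full((16, 16, 16), 2.5)
        out = butterworth_filter(vol, order=5, cutoff_cm=0.44)
        assert np.allclose(out, vol, atol=1e-9)

    def test_gain_matches_closed_form_everywhere(self):
        # filter a delta and compare its spectrum with the analytic gain
        n, vox, cutoff, order = 32, 0.68, 0.44, 5
        delta = np.zeros((n, n, n))
        delta[0, 0, 0] = 1.0
        out = butterworth_filter(delta, order=order, cutoff_cm=cutoff,
                                 voxel_size_cm=vox)
        spectrum = np.fft.rfftn(out)
        f = [np.fft.fftfreq(n, d=vox)] * 2 + [np.fft.rfftfreq(n, d=vox)]
        fx, fy, fz = np.meshgrid(*f, indexing="ij")
        nu = np.sqrt(fx**2 + fy**2 + fz**2)
        gain = 1.0 / np.sqrt(1.0 + (nu / cutoff) ** (2 * order))
        assert np.max(np.abs(np.real(spectrum) - gain)) <= 1e-9

    def test_half_power_at_cutoff(self):
        order, cutoff = 5, 0.44
        gain = 1.0 / np.sqrt(1.0 + (cutoff / cutoff) ** (2 * order))
        assert gain == pytest.approx(1 / np.sqrt(2), abs=1e-12)
        nus = np.linspace(0, 0.7, 200)
        gains = 1.0 / np.sqrt(1.0 + (nus / cutoff) ** (2 * order))
        assert np.all(np.diff(gains) <= 0)

    def test_cutoff_above_nyquist_warns_and_clamps(self):
        vol = np.random.default_rng(0).random((8, 8, 8))
        with pytest.warns(UserWarning, match="Nyquist"):
            butterworth_filter(vol, cutoff_cm=2.0, voxel_size_cm=0.68)


class TestReorientation:
    def _heart(self, axis, anterior=(0.0, -1.0, 0.0)):
        return ph.HeartGeometry(
            center_cm=(0.0, 0.0, 0.0), long_axis=axis,
            r_outer_cm=3.0, r_inner_cm=2.0,
            long_outer_cm=4.5, long_inner_cm=3.5, anterior=anterior,
        )

    def test_aligned_axis_is_identity(self, rng):
        vol = rng.random((32, 32, 32))
        heart = self._heart((0.0, 0.0, 1.0), anterior=(0.0, 1.0, 0.0))
        out = reorient_short_axis(vol, heart, ph.VolumeGrid(shape=(32,) * 3))
        assert np.max(np.abs(out - vol)) <= 1e-6

    def test_rotation_round_trip(self, rng):
        from scipy.ndimage import gaussian_filter

        vol = gaussian_filter(rng.random((32, 32, 32)), 2.0)
        heart = self._heart((0.5, -0.4, -0.77))
        grid = ph.VolumeGrid(shape=(32,) * 3)
        there = reorient_short_axis(vol, heart, grid)
        back = reorient_short_axis(there, heart, grid, inverse=True)
        core = (slice(8, 24),) * 3
        rel_rmse = np.sqrt(np.mean((back[core] - vol[core]) ** 2)) / np.sqrt(
            np.mean(vol[core] ** 2)
        )
        assert rel_rmse <= 0.02

    def test_centroid_maps_to_oracle_position(self):
        heart = self._heart((0.6, -0.5, -0.62))
        grid = ph.VolumeGrid(shape=(32,) * 3)
        point = np.array([20.0, 12.0, 18.0])
        mapped = short_axis_point(point, heart, grid)
        # brute-force: project the world offset onto the heart frame axes
        e1, e2, d = heart.basis()
        w = grid.voxel_to_world(point) - np.asarray(heart.center_cm)
        expected = (np.asarray(grid.shape) - 1) / 2.0 + np.array(
            [np.dot(w, e1), np.dot(w, e2), np.dot(w, d)]
        ) / grid.voxel_size_cm[0]
        assert np.allclose(mapped, expected, atol=1e-9)

    def test_degenerate_axis_rejected(self):
        with pytest.raises(ValueError):
            self._heart((0.0, 0.0, 0.0))


class TestExtractROI:
    def test_output_shape_and_centroid_value(self, rng):
        vol = rng.random((64, 64, 64)).astype(np.float32)
        roi = extract_roi(vol, (30.2, 33.4, 40.0))
        assert roi.shape == (32, 32)
        assert roi[16, 16] == vol[30, 33, 40]

    def test_translation_property(self, rng):
        vol = rng.random((64, 64, 64)).astype(np.float32)
        a = extract_roi(vol, (30, 30, 40))
        b = extract_roi(vol, (32, 33, 40))
        # shifting the centroid by (+2, +3) shifts the contents by (-2, -3)
        assert np.array_equal(a[10:20, 10:20], b[8:18, 7:17])

    def test_out_of_volume_centroid_rejected(self, rng):
        vol = rng.random((16, 16, 16))
        with pytest.raises(ValueError):
            extract_roi(vol, (20, 8, 8))

    def test_boundary_crop_zero_pads_with_warning(self, rng):
        vol = rng.random((64, 64, 64)).astype(np.float32)
        with pytest.warns(UserWarning, match="zero-padding"):
            roi = extract_roi(vol, (2, 2, 10))
        assert roi.shape == (32, 32)
        assert np.all(roi[:14, 0] == 0)
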