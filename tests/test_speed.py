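"""Kernel grids, direction detection, directional ACF and cosinusoid fits."""

import numpy as np
import pytest

import vswe3d as v

from conftest import make_plane_field


def angular_error_deg(direction, reference):
    reference = np.asarray(reference, float)
    reference = reference / np.linalg.norm(reference)
    return np.degrees(np.arccos(np.clip(np.dot(direction, reference), -1.0, 1.0)))


class TestKernelGrid:
    def test_cubic_mask_lattice_counts(self):
        # 10 mm cube, 2 mm kernel, 0.5 mm spacing -> floor((10-2)/0.5)+1 = 17/axis
        mask = np.ones((100, 100, 100), dtype=bool)
        grid = v.build_kernel_grid(mask, (0.1, 0.1, 0.1), 2.0, 0.5)
        assert grid.shape == (17, 17, 17)
        assert grid.n_points == 17 ** 3

    def test_spacing_equal_to_kernel_tiles_without_overlap(self):
        mask = np.ones((100, 100, 100), dtype=bool)
        grid = v.build_kernel_grid(mask, (0.1, 0.1, 0.1), 2.0, 2.0)
        assert grid.shape == (5, 5, 5)
        assert np.allclose(np.diff(grid.x_mm), 2.0)

    def test_single_voxel_mask_gives_single_point(self):
        mask = np.zeros((40, 40, 40), dtype=bool)
        mask[20, 20, 20] = True
        grid = v.build_kernel_grid(mask, (0.1, 0.1, 0.1), 2.0, 0.5)
        assert grid.shape == (1, 1, 1)
        assert grid.n_points == 1
        assert grid.z_mm[0] == pytest.approx(2.0)

    def test_points_outside_mask_are_dropped(self):
        # two slabs with a gap: lattice spans the bbox, gap points are dropped
        mask = np.zeros((100, 100, 100), dtype=bool)
        mask[:, :30, :] = True
        mask[:, 70:, :] = True
        grid = v.build_kernel_grid(mask, (0.1, 0.1, 0.1), 2.0, 0.5)
        assert 0 < grid.n_points < np.prod(grid.shape)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            v.build_kernel_grid(np.zeros((10, 10, 10), bool), (0.1, 0.1, 0.1), 2.0, 0.5)


class TestDetectDirection:
    def test_plane_wave_along_x(self, plane_field_700):
        field, _ = plane_field_700
        d = v.detect_direction(field, (3.0, 3.0, 3.0), 2.0)
        assert angular_error_deg(d, (0, 1, 0)) < 0.5

    def test_oblique_plane_wave(self):
        field, _ = make_plane_field(direction=(0, 1, 1))
        d = v.detect_direction(field, (3.0, 3.0, 3.0), 2.0)
        assert angular_error_deg(d, (0, 1, 1)) < 1.0

    def test_zero_amplitude_kernel_is_invalid(self, plane_field_700):
        field, _ = plane_field_700
        dead = v.WaveField(phasor=np.zeros_like(field.phasor),
                           pitch_mm=field.pitch_mm, frequency_hz=field.frequency_hz)
        assert v.detect_direction(dead, (3.0, 3.0, 3.0), 2.0) is None

    def test_standing_wave_node_is_invalid(self):
        phantom = v.make_phantom("homogeneous", extent_mm=(4, 6, 4),
                                 pitch_mm=(0.1, 0.1, 0.1), c_s=4.0)
        fwd = v.SourceSpec(frequency_hz=700.0, kind="plane", direction=(0, 1, 0))
        bwd = v.SourceSpec(frequency_hz=700.0, kind="plane", direction=(0, -1, 0))
        field = v.synthesize_wavefield(phantom, [fwd, bwd])
        # opposing gradients in a standing wave: incoherent kernel
        assert v.detect_direction(field, (2.0, 3.0, 2.0), 2.0) is None


class TestAcfProfile:
    def test_plane_wave_profile_is_cosine(self, plane_field_700):
        field, _ = plane_field_700
        lags, profile = v.kernel_acf_profile(field, (3.0, 3.0, 3.0), 2.0, (0, 1, 0))
        lam = 4000.0 / 700.0
        assert np.abs(profile - np.cos(2 * np.pi * lags / lam)).max() < 0.02

    def test_profile_starts_at_one(self, plane_field_700):
        field, _ = plane_field_700
        _, profile = v.kernel_acf_profile(field, (3.0, 3.0, 3.0), 2.0, (0, 1, 0))
        assert profile[0] == pytest.approx(1.0, abs=1e-12)

    def test_white_noise_profile_is_delta_at_zero(self):
        rng = np.random.default_rng(77)
        phasor = rng.standard_normal((40, 40, 40)) + 1j * rng.standard_normal((40, 40, 40))
        field = v.WaveField(phasor=phasor, pitch_mm=(0.1, 0.1, 0.1), frequency_hz=700.0)
        lags, profile = v.kernel_acf_profile(field, (2.0, 2.0, 2.0), 2.0, (0, 1, 0))
        assert profile[0] == pytest.approx(1.0)
        # ~21³ voxels contribute at short lags; 3/sqrt(pairs) is ≲0.15 at the tail
        assert np.abs(profile[1:]).max() < 0.15


class TestCosinusoidFit:
    @pytest.mark.parametrize("lam_mm,freq,c_expected",
                             [(40.0 / 7.0, 700.0, 4.0), (4.0, 1000.0, 4.0)])
    def test_exact_cosine_recovers_c_equals_lambda_f(self, lam_mm, freq, c_expected):
        lags = 0.1 * np.arange(20)
        profile = np.cos(2 * np.pi * lags / lam_mm)
        fit = v.fit_cosinusoid(lags, profile, freq)
        assert fit.c_s == pytest.approx(c_expected, rel=1e-6)
        assert fit.gof < 1e-6
        assert fit.valid

    def test_noisy_profile_within_3pct_of_brute_force_oracle(self):
        lam_true = 5.0
        lags = 0.1 * np.arange(20)
        rng = np.random.default_rng(11)
        profile = np.cos(2 * np.pi * lags / lam_true) + rng.normal(0, 0.05, lags.size)
        fit = v.fit_cosinusoid(lags, profile, 800.0)
        # oracle: dense 1D grid search with closed-form amplitude
        best = (np.inf, None)
        for lam in np.linspace(0.625, 18.75, 20000):
            basis = np.cos(2 * np.pi * lags / lam)
            b = np.clip(profile @ basis / (basis @ basis), 1e-6, 1.0)
            rss = np.sum((profile - b * basis) ** 2)
            if rss < best[0]:
                best = (rss, lam)
        assert abs(fit.wavelength_mm - lam_true) / lam_true < 0.03
        assert fit.wavelength_mm == pytest.approx(best[1], rel=1e-3)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="lag samples"):
            v.fit_cosinusoid(np.arange(5.0), np.ones(5), 700.0)

    def test_wavelength_pinned_at_bound_is_invalid(self):
        lags = 0.1 * np.arange(20)
        profile = np.ones(20)  # "infinite wavelength": pins λ at the upper bound
        fit = v.fit_cosinusoid(lags, profile, 700.0)
        assert not fit.valid


class TestBuildSpeedMap:
    def test_homogeneous_phantom_within_2pct(self, plane_field_700):
        field, phantom = plane_field_700
        mask = np.zeros(phantom.grid_shape, bool)
        mask[10:50, 10:50, 10:50] = True
        grid = v.build_kernel_grid(mask, phantom.voxel_pitch_mm, 2.0, 1.0)
        smap = v.build_speed_map(field, grid)
        speeds = smap.valid_speeds()
        assert speeds.size == grid.n_points
        assert np.abs(speeds - 4.0).max() / 4.0 < 0.02

    def test_rotation_equivariance(self):
        speeds = {}
        for direction in [(0, 1, 0), (0, 1, 1), (1, 1, 1)]:
            field, _ = make_plane_field(direction=direction)
            d = v.detect_direction(field, (3.0, 3.0, 3.0), 2.0)
            lags, profile = v.kernel_acf_profile(field, (3.0, 3.0, 3.0), 2.0, d)
            speeds[direction] = v.fit_cosinusoid(lags, profile, 700.0).c_s
        values = np.array(list(speeds.values()))
        assert np.abs(values - 4.0).max() / 4.0 < 0.02

    def test_inclusion_core_and_background_medians(self):
        phantom = v.make_phantom("inclusion", extent_mm=(12.0, 12.0, 8.0),
                                 pitch_mm=(0.1, 0.1, 0.2), background_c_s=4.0,
                                 inclusion_c_s=6.0, radius_mm=2.0)
        src = v.SourceSpec(frequency_hz=700.0, kind="plane", direction=(0, 1, 0))
        field = v.synthesize_wavefield(phantom, [src])
        centre = np.array([5.95, 5.95, 3.9])
        z, x, y = phantom._meshgrid()
        r2 = (z - centre[0]) ** 2 + (x - centre[1]) ** 2 + (y - centre[2]) ** 2
        core = v.build_kernel_grid(r2 <= 1.0 ** 2, phantom.voxel_pitch_mm, 2.0, 0.5)
        core_map = v.build_speed_map(field, core)
        assert abs(core_map.median_speed() - 6.0) / 6.0 < 0.05
        bg_mask = np.zeros(phantom.grid_shape, bool)
        bg_mask[15:105, 15:35, 10:30] = True  # strip ahead of the inclusion
        bg = v.build_kernel_grid(bg_mask, phantom.voxel_pitch_mm, 2.0, 1.0)
        bg_map = v.build_speed_map(field, bg)
        assert abs(bg_map.median_speed() - 4.0) / 4.0 < 0.05

    def test_gof_grows_with_phasor_noise(self):
        field, phantom = make_plane_field(extent_mm=(4, 4, 4))
        mask = np.zeros(phantom.grid_shape, bool)
        mask[15:25, 15:25, 15:25] = True
        grid = v.build_kernel_grid(mask, phantom.voxel_pitch_mm, 2.0, 1.0)
        gofs = []
        for i, sigma in enumerate((0.0, 0.3, 1.0)):
            rng = np.random.default_rng(50 + i)
            noisy = v.WaveField(
                phasor=field.phasor + sigma * (rng.standard_normal(field.shape)
                                               + 1j * rng.standard_normal(field.shape)),
                pitch_mm=field.pitch_mm, frequency_hz=field.frequency_hz)
            smap = v.build_speed_map(noisy, grid)
            gofs.append(np.median(smap.gof[smap.valid]))
        assert gofs[0] <= gofs[1] <= gofs[2]

    def test_dispersion_slope_recovered_from_per_frequency_maps(self):
        slope_true = 1.0e-3  # m/s per Hz
        medians = []
        for f in (700.0, 1000.0, 1200.0):
            c_f = 4.0 + slope_true * (f - 700.0)
            field, phantom = make_plane_field(c_s=c_f, frequency_hz=f,
                                              extent_mm=(4, 4, 4))
            mask = np.zeros(phantom.grid_shape, bool)
            mask[15:25, 15:25, 15:25] = True
            grid = v.build_kernel_grid(mask, phantom.voxel_pitch_mm, 2.0, 1.0)
            medians.append((f, v.build_speed_map(field, grid).median_speed()))
        slope = v.dispersion_slope(medians)
        assert abs(slope - slope_true) / slope_true < 0.10

    def test_zero_field_all_points_invalid(self):
        field, phantom = make_plane_field(extent_mm=(4, 4, 4), amplitude_um=0.0)
        mask = np.ones(phantom.grid_shape, bool)
        grid = v.build_kernel_grid(mask, phantom.voxel_pitch_mm, 2.0, 1.0)
        with pytest.warns(UserWarning, match="valid"):
            smap = v.build_speed_map(field, grid)
        assert not smap.valid.any()
        assert np.isnan(smap.median_speed())
        assert np.isnan(v.tumour_median(smap))
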