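"""Wave-field synthesis, displacement sampling and phantom construction."""

import numpy as np
import pytest

import vswe3d as v

from conftest import make_plane_field


class TestWavefield:
    def test_plane_wave_phase_step(self):
        # k = 2πf/c: 700 Hz at 4 m/s -> 1.0996 rad per mm along propagation
        field, _ = make_plane_field(c_s=4.0, frequency_hz=700.0)
        step = np.angle(field.phasor[30, 40, 30] * np.conj(field.phasor[30, 30, 30]))
        assert step == pytest.approx(-2 * np.pi * 700.0 / 4000.0, abs=1e-9)

    def test_phase_is_affine_along_propagation(self):
        field, _ = make_plane_field(c_s=4.0, frequency_hz=700.0)
        x_mm = 0.1 * np.arange(field.shape[1])
        phase = np.unwrap(np.angle(field.phasor[30, :, 30]))
        coeffs = np.polyfit(x_mm, phase, 1)
        assert coeffs[0] == pytest.approx(-2 * np.pi * 700.0 / 4000.0, rel=1e-9)
        residual = phase - np.polyval(coeffs, x_mm)
        assert np.abs(residual).max() < 1e-9

    def test_zero_amplitude_source_gives_zero_field(self):
        field, _ = make_plane_field(amplitude_um=0.0)
        assert np.all(field.phasor == 0)

    def test_superposition_is_linear(self):
        phantom = v.make_phantom("homogeneous", extent_mm=(4, 4, 4),
                                 pitch_mm=(0.2, 0.2, 0.2), c_s=4.0)
        s1 = v.SourceSpec(frequency_hz=700.0, kind="point", position_mm=(2, -3, 2),
                          amplitude_um=8.0)
        s2 = v.SourceSpec(frequency_hz=700.0, kind="point", position_mm=(-3, 2, 2),
                          amplitude_um=5.0, phase_rad=1.0)
        both = v.synthesize_wavefield(phantom, [s1, s2]).phasor
        separate = (v.synthesize_wavefield(phantom, [s1]).phasor
                    + v.synthesize_wavefield(phantom, [s2]).phasor)
        scale = np.abs(separate).max()
        assert np.abs(both - separate).max() < 1e-12 * scale

    def test_counter_propagating_waves_have_nodes_half_wavelength_apart(self):
        # standing wave: amplitude envelope nodes spaced λ/2
        phantom = v.make_phantom("homogeneous", extent_mm=(2, 12, 2),
                                 pitch_mm=(0.1, 0.05, 0.1), c_s=4.0)
        fwd = v.SourceSpec(frequency_hz=1000.0, kind="plane", direction=(0, 1, 0))
        bwd = v.SourceSpec(frequency_hz=1000.0, kind="plane", direction=(0, -1, 0))
        field = v.synthesize_wavefield(phantom, [fwd, bwd])
        profile = field.amplitude[10, :, 10]
        x_mm = 0.05 * np.arange(profile.size)
        minima = [x_mm[i] for i in range(1, profile.size - 1)
                  if profile[i] < profile[i - 1] and profile[i] <= profile[i + 1]
                  and profile[i] < 0.1 * profile.max()]
        lam = 4000.0 / 1000.0  # mm
        assert len(minima) >= 3
        assert np.allclose(np.diff(minima), lam / 2, atol=0.06)

    def test_point_source_attenuation_and_spreading(self):
        alpha = 0.3  # Np/mm
        phantom = v.make_phantom("homogeneous", extent_mm=(4, 8, 4),
                                 pitch_mm=(0.1, 0.1, 0.1), c_s=4.0, alpha=alpha)
        src = v.SourceSpec(frequency_hz=700.0, kind="point",
                           position_mm=(1.9, -2.0, 1.9), amplitude_um=10.0)
        field = v.synthesize_wavefield(phantom, [src])
        # two voxels on the ray through the source, along +X
        a1, a2 = field.amplitude[19, 20, 19], field.amplitude[19, 60, 19]
        r1, r2 = 2.0 + 0.1 * 20, 2.0 + 0.1 * 60
        expected = np.sqrt(r1 / r2) * np.exp(-alpha * (r2 - r1))
        assert a2 / a1 == pytest.approx(expected, rel=1e-9)

    def test_mixed_drive_frequencies_rejected(self):
        phantom = v.make_phantom("homogeneous", extent_mm=(2, 2, 2),
                                 pitch_mm=(0.2, 0.2, 0.2))
        s1 = v.SourceSpec(frequency_hz=700.0, kind="plane")
        s2 = v.SourceSpec(frequency_hz=1000.0, kind="plane")
        with pytest.raises(ValueError, match="frequency"):
            v.synthesize_wavefield(phantom, [s1, s2])

    def test_source_on_voxel_rejected(self):
        phantom = v.make_phantom("homogeneous", extent_mm=(2, 2, 2),
                                 pitch_mm=(0.2, 0.2, 0.2))
        src = v.SourceSpec(frequency_hz=700.0, kind="point",
                           position_mm=(0.8, 0.8, 0.8))  # a voxel centre
        with pytest.raises(ValueError, match="singular"):
            v.synthesize_wavefield(phantom, [src])

    def test_no_sources_rejected(self):
        phantom = v.make_phantom("homogeneous", extent_mm=(2, 2, 2),
                                 pitch_mm=(0.2, 0.2, 0.2))
        with pytest.raises(ValueError):
            v.synthesize_wavefield(phantom, [])


class TestDisplacementSeries:
    def test_noiseless_amplitude(self):
        field, _ = make_plane_field(extent_mm=(1, 1, 1), pitch_mm=(0.2, 0.2, 0.2))
        d = v.synthesize_displacement_series(field, periods=10)
        assert d.data.max() == pytest.approx(10.0, rel=1e-6)
        assert d.sample_rate_hz == 6 * 700.0

    def test_interfering_tone_gives_exactly_two_spectral_lines(self):
        field, _ = make_plane_field(extent_mm=(1, 1, 1), pitch_mm=(0.2, 0.2, 0.2),
                                    frequency_hz=700.0)
        noise = v.NoiseSpec(sigma_um=0.0, tones=[(1400.0, 10.0)], seed=0)
        d = v.synthesize_displacement_series(field, periods=10, noise=noise)
        spectrum = np.abs(np.fft.rfft(d.data[0, 0, 0]))
        lines = np.nonzero(spectrum > 1e-6 * spectrum.max())[0]
        assert set(lines) == {10, 20}  # drive bin (10 periods) and its double

    def test_seeded_noise_is_reproducible(self):
        field, _ = make_plane_field(extent_mm=(1, 1, 1), pitch_mm=(0.2, 0.2, 0.2))
        noise = v.NoiseSpec(sigma_um=0.5, seed=42)
        d1 = v.synthesize_displacement_series(field, periods=5, noise=noise)
        d2 = v.synthesize_displacement_series(field, periods=5, noise=noise)
        assert np.array_equal(d1.data, d2.data)

    def test_too_few_periods_rejected(self):
        field, _ = make_plane_field(extent_mm=(1, 1, 1), pitch_mm=(0.2, 0.2, 0.2))
        with pytest.raises(ValueError, match="period"):
            v.synthesize_displacement_series(field, periods=1)
        with pytest.raises(ValueError, match="samples"):
            v.synthesize_displacement_series(field, periods=5, samples_per_period=2)


class TestPhantoms:
    def test_homogeneous_truth_map_is_uniform(self):
        phantom = v.make_phantom("homogeneous", extent_mm=(12, 12, 10), c_s=4.0)
        truth = phantom.speed_map()
        assert truth.shape == (120, 120, 50)
        assert np.all(truth == 4.0)
        assert phantom.mask.all()

    def test_inclusion_voxel_counts_match_analytic_sphere(self):
        # oracle: direct enumeration of voxel centres inside the sphere
        phantom = v.make_phantom("inclusion", extent_mm=(8, 8, 6),
                                 pitch_mm=(0.2, 0.2, 0.2), background_c_s=4.0,
                                 inclusion_c_s=6.0, radius_mm=2.0)
        truth = phantom.speed_map()
        z, x, y = v.axis_coordinates(phantom.grid_shape, phantom.voxel_pitch_mm)
        cz, cx, cy = [0.5 * (c[-1]) for c in (z, x, y)]
        count = 0
        for zz in z:
            for xx in x:
                for yy in y:
                    if (zz - cz) ** 2 + (xx - cx) ** 2 + (yy - cy) ** 2 <= 4.0:
                        count += 1
        assert (truth == 6.0).sum() == count
        assert set(np.unique(truth)) == {4.0, 6.0}

    def test_treated_pair_core_change(self):
        baseline, followup = v.make_phantom("treated-pair", extent_mm=(8, 8, 6),
                                            c_s=4.0, core_change_pct=-25.0)
        assert np.all(baseline.speed_map() == 4.0)
        core = followup.speed_map()
        assert core.min() == pytest.approx(3.0)
        assert core.max() == pytest.approx(4.0)
        assert np.array_equal(baseline.mask, followup.mask)
        assert baseline.mask.any() and not baseline.mask.all()

    def test_nonphysical_speed_rejected(self):
        with pytest.raises(ValueError):
            v.make_phantom("homogeneous", c_s=-1.0)
        with pytest.raises(ValueError):
            v.make_phantom("inclusion", extent_mm=(6, 6, 6), radius_mm=5.0)
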