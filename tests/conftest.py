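import numpy as np
import pytest

import vswe3d as v


def make_plane_field(c_s=4.0, frequency_hz=700.0, extent_mm=(6.0, 6.0, 6.0),
                     pitch_mm=(0.1, 0.1, 0.1), direction=(0.0, 1.0, 0.0),
                     amplitude_um=10.0):
    """Noiseless plane-wave phasor field in a homogeneous phantom."""
    phantom = v.make_phantom("homogeneous", extent_mm=extent_mm,
                             pitch_mm=pitch_mm, c_s=c_s)
    source = v.SourceSpec(frequency_hz=frequency_hz, kind="plane",
                          direction=direction, amplitude_um=amplitude_um)
    return v.synthesize_wavefield(phantom, [source]), phantom


def uniform_series(amplitude_um, frequency_hz, periods=10, samples_per_period=6,
                   shape=(2, 2, 2), extra=None):
    """DisplacementVolume with the same sinusoid at every voxel.

    ``extra`` is an optional callable t -> additional displacement (µm).
    """
    prf = samples_per_period * frequency_hz
    t = np.arange(periods * samples_per_period) / prf
    series = amplitude_um * np.sin(2 * np.pi * frequency_hz * t)
    if extra is not None:
        series = series + extra(t)
    data = np.broadcast_to(series, shape + series.shape).copy()
    return v.DisplacementVolume(data=data, pitch_mm=(0.1, 0.1, 0.1),
                                sample_rate_hz=prf, drive_frequency_hz=frequency_hz)


@pytest.fixture(scope="session")
def plane_field_700():
    """4 m/s plane wave along +X at 700 Hz, 6 mm iso cube at 0.1 mm pitch."""
    field, phantom = make_plane_field()
    return field, phantom
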