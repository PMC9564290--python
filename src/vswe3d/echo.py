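"""IQ echo synthesis and phase-shift axial displacement estimation.

The forward model phase-modulates a seeded speckle pattern with the axial
tissue displacement,

    IQ(v, j) = A(v) · exp(i[φ(v) + (4π f_c / c_us) · d(v, j)]) + n(v, j),

where A, φ are Rayleigh-amplitude/uniform-phase speckle (constant over slow
time) and n is complex white noise at a stated SNR.  The inverse is a
lag-one slow-time autocorrelation (Kasai-style) estimator: pulse-to-pulse
phase shifts, averaged coherently over a short axial window, are scaled by
c_us/(4π f_c) and accumulated into displacement.  Beamforming is not
modelled; IQ lives directly on the reconstructed voxel grid.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
from scipy.ndimage import uniform_filter1d

from .containers import DisplacementVolume, IQVolume

__all__ = ["synthesize_iq", "estimate_axial_displacement", "AliasingWarning"]

DEFAULT_CENTRE_FREQUENCY_HZ = 18.5e6
DEFAULT_SOUND_SPEED_M_S = 1540.0
#: axial coherent-averaging window for the phase-shift estimator, mm.
#: Well below the shear wavelengths mapped here (3–11 mm) so the wave is not blurred.
DEFAULT_AXIAL_WINDOW_MM = 0.5


class AliasingWarning(UserWarning):
    """Pulse-to-pulse IQ phase step reached ±π: displacement is ambiguous."""


def synthesize_iq(displacement: DisplacementVolume,
                  centre_frequency_hz: float = DEFAULT_CENTRE_FREQUENCY_HZ,
                  sound_speed_m_s: float = DEFAULT_SOUND_SPEED_M_S,
                  seed: int = 0,
                  snr_db: Optional[float] = None) -> IQVolume:
    """Phase-modulate seeded speckle with an axial displacement series.

    ``snr_db`` is the ratio of mean speckle power to complex noise power;
    ``None`` disables noise.  Warns (``AliasingWarning``) if any consecutive
    displacement step maps to a phase step of magnitude ≥ π.
    """
    d_um = displacement.data
    rad_per_um = 4.0 * np.pi * centre_frequency_hz / sound_speed_m_s * 1e-6
    phase_mod = rad_per_um * d_um

    steps = np.abs(np.diff(phase_mod, axis=-1))
    if steps.size and steps.max() >= np.pi:
        warnings.warn("displacement causes pulse-to-pulse phase steps >= pi; "
                      "the phase-shift estimator will alias", AliasingWarning,
                      stacklevel=2)

    rng = np.random.default_rng(seed)
    spatial = d_um.shape[:3]
    amp = rng.rayleigh(scale=1.0, size=spatial)
    phi = rng.uniform(-np.pi, np.pi, size=spatial)
    iq = amp[..., None] * np.exp(1j * (phi[..., None] + phase_mod))

    if snr_db is not None:
        signal_power = np.mean(amp ** 2)
        noise_power = signal_power / 10.0 ** (snr_db / 10.0)
        sigma = np.sqrt(noise_power / 2.0)
        iq = iq + sigma * (rng.standard_normal(iq.shape)
                           + 1j * rng.standard_normal(iq.shape))

    return IQVolume(data=iq, pitch_mm=displacement.pitch_mm,
                    centre_frequency_hz=centre_frequency_hz,
                    sound_speed_m_s=sound_speed_m_s,
                    prf_hz=displacement.sample_rate_hz,
                    drive_frequency_hz=displacement.drive_frequency_hz)


def estimate_axial_displacement(iq: IQVolume,
                                axial_window_mm: float = DEFAULT_AXIAL_WINDOW_MM
                                ) -> DisplacementVolume:
    """Recover axial displacement from IQ data by lag-one autocorrelation.

    Per pulse-to-pulse interval the complex product IQ(j+1)·conj(IQ(j)) is
    averaged coherently over the axial window before taking the angle, the
    phase is scaled to µm, and increments are accumulated; the cumulative
    series is returned with its slow-time mean removed (integration drift
    does not reach the drive-frequency bin).  Voxels with zero IQ magnitude
    at any pulse are flagged invalid.
    """
    if iq.n_samples < 2:
        raise ValueError("need at least two slow-time samples")

    corr = iq.data[..., 1:] * np.conj(iq.data[..., :-1])

    window = max(int(round(axial_window_mm / iq.pitch_mm[0])), 1)
    if window > 1:
        corr = (uniform_filter1d(corr.real, size=window, axis=0, mode="nearest")
                + 1j * uniform_filter1d(corr.imag, size=window, axis=0, mode="nearest"))

    increments_um = iq.phase_to_displacement_um * np.angle(corr)
    d = np.concatenate([np.zeros(increments_um.shape[:3] + (1,)),
                        np.cumsum(increments_um, axis=-1)], axis=-1)
    d -= d.mean(axis=-1, keepdims=True)

    valid = (np.abs(iq.data) > 0.0).all(axis=-1)
    return DisplacementVolume(data=d, pitch_mm=iq.pitch_mm,
                              sample_rate_hz=iq.prf_hz,
                              drive_frequency_hz=iq.drive_frequency_hz,
                              valid=valid)
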