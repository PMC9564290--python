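"""Drive-frequency phasor maps and the Conformance quality metric.

The acquisition contract locks the PRF to an integer number of samples per
vibration period and records whole periods, so the drive tone falls on an
exact FFT bin (bin index = number of recorded periods).  ``extract_phasor``
reads amplitude and phase off that bin; ``conformance`` reports the
percentage of total detected vibrational energy found there,

    C(%) = 100 · |S_f|² / Σ_i |S_i|²,

with the sum over the one-sided spectrum (bins 1 .. N/2, DC excluded:
detrending drives DC to ~0 and only oscillatory energy counts as
"vibrational").
"""

from __future__ import annotations

import numpy as np

from .containers import ConformanceMap, DisplacementVolume, WaveField

__all__ = ["extract_phasor", "conformance", "drive_bin_index"]


def drive_bin_index(d: DisplacementVolume) -> int:
    """FFT bin of the drive tone; rejects misaligned acquisitions.

    Raises ``ValueError`` if the drive frequency is not an exact FFT bin —
    the hardware contract (transducer synchronised to the source signal
    generator) guarantees alignment, so misalignment signals a broken input.
    """
    n = d.n_samples
    bin_exact = d.drive_frequency_hz * n / d.sample_rate_hz
    k = int(round(bin_exact))
    if abs(bin_exact - k) > 1e-9 or k < 1 or k > n // 2:
        raise ValueError(
            f"drive frequency {d.drive_frequency_hz} Hz is not an exact FFT bin "
            f"(N={n}, PRF={d.sample_rate_hz} Hz): got bin {bin_exact}")
    return k


def extract_phasor(d: DisplacementVolume) -> WaveField:
    """FFT the displacement-versus-time data and read off the drive bin.

    Returns the complex phasor P with |P| equal to the true sinusoid
    amplitude (µm) for noiseless input and the phase convention
    d(t) = Re{P · exp(+i 2π f t)}.
    """
    k = drive_bin_index(d)
    n = d.n_samples
    spectrum = np.fft.rfft(d.data, axis=-1)
    p = (2.0 / n) * spectrum[..., k]
    return WaveField(phasor=p, pitch_mm=d.pitch_mm, frequency_hz=d.drive_frequency_hz)


def conformance(d: DisplacementVolume) -> ConformanceMap:
    """Per-voxel Conformance C (%) of the displacement spectrum.

    Voxels with zero total oscillatory energy are undefined (NaN, flagged),
    not zero.
    """
    k = drive_bin_index(d)
    n = d.n_samples
    spectrum = np.fft.rfft(d.data, axis=-1)
    power = np.abs(spectrum) ** 2
    # one-sided bins 1 .. N/2 (rfft already stops at N/2); DC excluded
    total = power[..., 1:].sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = 100.0 * power[..., k] / total
    defined = total > 0.0
    c = np.where(defined, c, np.nan)
    return ConformanceMap(data=c, pitch_mm=d.pitch_mm,
                          frequency_hz=d.drive_frequency_hz, defined=defined)
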