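"""Core data containers for the 3D vibrational shear wave elastography chain.

Axis convention (used everywhere in this package): volumes are indexed
``(z, x, y)`` = (axial, lateral, elevational), 0-based voxel indices, with
voxel-centre coordinates in millimetres.  Time-resolved volumes carry the
slow-time (pulse-to-pulse) axis last: ``(z, x, y, t)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "axis_coordinates",
    "WaveField",
    "DisplacementVolume",
    "IQVolume",
    "ConformanceMap",
]


def axis_coordinates(shape: tuple[int, int, int],
                     pitch_mm: tuple[float, float, float]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel-centre coordinates in mm along (z, x, y) for a regular grid."""
    return tuple(np.arange(n) * p for n, p in zip(shape, pitch_mm))


def _check_pitch(pitch_mm) -> tuple[float, float, float]:
    pitch = tuple(float(p) for p in pitch_mm)
    if len(pitch) != 3 or any(p <= 0 for p in pitch):
        raise ValueError(f"voxel pitch must be three positive values, got {pitch_mm!r}")
    return pitch


@dataclass
class WaveField:
    """Complex displacement phasor at the drive frequency on a regular 3D grid.

    ``phasor`` holds amplitude (µm) and phase (rad) of the tissue displacement
    at the vibration frequency: the real displacement at a voxel is
    ``Re{phasor * exp(+i 2π f t)}``.
    """

    phasor: np.ndarray                      # complex, (nz, nx, ny), µm
    pitch_mm: tuple[float, float, float]
    frequency_hz: float

    def __post_init__(self) -> None:
        self.phasor = np.asarray(self.phasor, dtype=complex)
        if self.phasor.ndim != 3:
            raise ValueError("WaveField phasor must be 3D (z, x, y)")
        self.pitch_mm = _check_pitch(self.pitch_mm)
        if self.frequency_hz <= 0:
            raise ValueError("drive frequency must be positive")

    @property
    def amplitude(self) -> np.ndarray:
        """Displacement amplitude |P| in µm."""
        return np.abs(self.phasor)

    @property
    def phase(self) -> np.ndarray:
        """Displacement phase arg(P) in (−π, π]."""
        return np.angle(self.phasor)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.phasor.shape

    def coordinates_mm(self):
        return axis_coordinates(self.shape, self.pitch_mm)


@dataclass
class DisplacementVolume:
    """Axial tissue displacement (µm) over (z, x, y, slow-time).

    Slow time is sampled at ``sample_rate_hz`` (the PRF), phase-coherent
    across elevational slices (common trigger at drive-phase zero).
    """

    data: np.ndarray                        # µm, (nz, nx, ny, nt)
    pitch_mm: tuple[float, float, float]
    sample_rate_hz: float                   # PRF
    drive_frequency_hz: float
    valid: Optional[np.ndarray] = None      # bool, (nz, nx, ny); None == all valid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DisplacementVolume data must be 4D (z, x, y, t)")
        if self.data.shape[-1] < 2:
            raise ValueError("need at least two slow-time samples")
        self.pitch_mm = _check_pitch(self.pitch_mm)
        if self.sample_rate_hz <= 0 or self.drive_frequency_hz <= 0:
            raise ValueError("PRF and drive frequency must be positive")
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.data.shape[:3]:
                raise ValueError("valid mask shape must match the spatial grid")

    @property
    def n_samples(self) -> int:
        return self.data.shape[-1]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz

    @property
    def samples_per_period(self) -> float:
        return self.sample_rate_hz / self.drive_frequency_hz


@dataclass
class IQVolume:
    """Complex demodulated (in-phase/quadrature) echo data over (z, x, y, slow-time).

    Slow-time phase tracks axial displacement: a displacement step ``d``
    between pulses advances the IQ phase by ``(4π f_c / c_us) · d``.
    """

    data: np.ndarray                        # complex, (nz, nx, ny, nt)
    pitch_mm: tuple[float, float, float]
    centre_frequency_hz: float              # f_c, e.g. 18.5 MHz
    sound_speed_m_s: float                  # c_us, e.g. 1540 m/s
    prf_hz: float
    drive_frequency_hz: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 4:
            raise ValueError("IQVolume data must be 4D (z, x, y, t)")
        self.pitch_mm = _check_pitch(self.pitch_mm)
        if self.centre_frequency_hz <= 0:
            raise ValueError("centre frequency must be positive")
        if self.sound_speed_m_s <= 0:
            raise ValueError("sound speed must be positive")
        if self.prf_hz <= 0 or self.drive_frequency_hz <= 0:
            raise ValueError("PRF and drive frequency must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[-1]

    @property
    def phase_to_displacement_um(self) -> float:
        """µm of axial displacement per radian of pulse-to-pulse IQ phase."""
        return self.sound_speed_m_s / (4.0 * np.pi * self.centre_frequency_hz) * 1e6


@dataclass
class ConformanceMap:
    """Per-voxel Conformance C (%) — the share of detected vibrational
    spectral energy found at the drive frequency.  Undefined voxels (zero
    total energy) carry NaN and ``defined == False``."""

    data: np.ndarray                        # float %, (nz, nx, ny), NaN where undefined
    pitch_mm: tuple[float, float, float]
    frequency_hz: float
    defined: np.ndarray = field(default=None)  # bool, (nz, nx, ny)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("ConformanceMap data must be 3D (z, x, y)")
        self.pitch_mm = _check_pitch(self.pitch_mm)
        if self.defined is None:
            self.defined = np.isfinite(self.data)
        else:
            self.defined = np.asarray(self.defined, dtype=bool)
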