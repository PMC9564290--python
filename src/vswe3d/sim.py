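"""Synthetic shear-wave fields and phantoms with known ground truth.

This module stands in for the acquisition hardware (signal generator,
mini-shakers, skin contactors): it produces the complex displacement phasor
a continuous vibrational source would set up in tissue, the sampled
displacement-versus-time series the ultrasound system would observe, and
phantoms (ground-truth shear-speed maps plus tumour masks) for end-to-end
testing.

Model
-----
Each source contributes a travelling wave

    P(r) = A0 · g(r) · exp(−∫α ds) · exp(i(φ0 − ∫k ds)),    k = 2πf / c_s,

with the phase and attenuation integrals taken along the straight ray from
the source to the voxel (no refraction or diffraction — the estimator, not
the propagation physics, is the object under test here).  ``g`` is the
geometric spreading factor: 1/√r for a point source (cylindrical-like decay
near a rod contactor, with A0 referenced at r = 1 mm) or 1 for a plane wave.
Superposition over sources is linear; all sources must share one drive
frequency.  The physical displacement is ``Re{P · exp(+i 2π f t)}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .containers import DisplacementVolume, WaveField, axis_coordinates

__all__ = [
    "Region",
    "PhantomSpec",
    "SourceSpec",
    "NoiseSpec",
    "synthesize_wavefield",
    "synthesize_displacement_series",
    "make_phantom",
]

#: default voxel pitch, mm per (z, x, y): 0.1 mm in-plane, 0.2 mm elevational step
DEFAULT_PITCH_MM = (0.1, 0.1, 0.2)


@dataclass
class Region:
    """A geometric primitive carrying local material properties.

    ``geometry`` is ``"box"`` (``size_mm`` = full edge lengths) or
    ``"ellipsoid"`` (``size_mm`` = semi-axes).  ``c_s`` is the true shear
    wave speed in m/s, ``alpha`` the amplitude attenuation in Np/mm.
    """

    geometry: str
    center_mm: tuple[float, float, float]
    size_mm: tuple[float, float, float]
    c_s: float
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if self.geometry not in ("box", "ellipsoid"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.c_s <= 0:
            raise ValueError("region shear speed must be positive")
        if self.alpha < 0:
            raise ValueError("attenuation must be non-negative")

    def contains(self, zz: np.ndarray, xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
        cz, cx, cy = self.center_mm
        sz, sx, sy = self.size_mm
        if self.geometry == "box":
            return ((np.abs(zz - cz) <= sz / 2)
                    & (np.abs(xx - cx) <= sx / 2)
                    & (np.abs(yy - cy) <= sy / 2))
        return (((zz - cz) / sz) ** 2 + ((xx - cx) / sx) ** 2 + ((yy - cy) / sy) ** 2) <= 1.0


@dataclass
class PhantomSpec:
    """A voxelised phantom: background medium overlaid by regions, plus an
    optional binary tumour mask used downstream to place measurement points."""

    grid_shape: tuple[int, int, int]                  # (nz, nx, ny)
    voxel_pitch_mm: tuple[float, float, float] = DEFAULT_PITCH_MM
    background_c_s: float = 4.0                       # m/s
    background_alpha: float = 0.0                     # Np/mm
    regions: list[Region] = field(default_factory=list)
    mask: Optional[np.ndarray] = None                 # bool, (nz, nx, ny)

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid shape must be positive")
        if any(p <= 0 for p in self.voxel_pitch_mm):
            raise ValueError("voxel pitch must be positive")
        if self.background_c_s <= 0:
            raise ValueError("background shear speed must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != tuple(self.grid_shape):
                raise ValueError("mask shape must match grid shape")

    def _meshgrid(self):
        z, x, y = axis_coordinates(self.grid_shape, self.voxel_pitch_mm)
        return np.meshgrid(z, x, y, indexing="ij")

    def speed_map(self) -> np.ndarray:
        """Ground-truth c_s (m/s) per voxel; regions overlay in list order."""
        zz, xx, yy = self._meshgrid()
        c = np.full(self.grid_shape, self.background_c_s, dtype=float)
        for region in self.regions:
            c[region.contains(zz, xx, yy)] = region.c_s
        return c

    def attenuation_map(self) -> np.ndarray:
        """Amplitude attenuation α (Np/mm) per voxel."""
        zz, xx, yy = self._meshgrid()
        a = np.full(self.grid_shape, self.background_alpha, dtype=float)
        for region in self.regions:
            a[region.contains(zz, xx, yy)] = region.alpha
        return a

    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * p for n, p in zip(self.grid_shape, self.voxel_pitch_mm))


@dataclass
class SourceSpec:
    """A vibrational source: a point contactor (``kind="point"``, position in
    mm, possibly outside the grid — the skin contactor) or an idealised plane
    wave (``kind="plane"``, unit propagation direction in (z, x, y))."""

    frequency_hz: float
    amplitude_um: float = 10.0
    phase_rad: float = 0.0
    kind: str = "point"
    position_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, float, float] = (0.0, 1.0, 0.0)

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError("drive frequency must be positive")
        if self.amplitude_um < 0:
            raise ValueError("displacement amplitude must be non-negative")
        if self.kind not in ("point", "plane"):
            raise ValueError(f"unknown source kind {self.kind!r}")
        d = np.asarray(self.direction, dtype=float)
        if self.kind == "plane":
            n = np.linalg.norm(d)
            if n == 0:
                raise ValueError("plane-wave direction must be non-zero")
            self.direction = tuple(d / n)


@dataclass
class NoiseSpec:
    """Displacement-domain disturbances: white noise per slow-time sample and
    optional spatially uniform interfering tones. ``seed`` fixes all
    pseudo-randomness."""

    sigma_um: float = 0.0
    tones: Sequence[tuple[float, float]] = ()   # (frequency Hz, amplitude µm)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_um < 0:
            raise ValueError("noise sigma must be non-negative")


def _ray_integrals(start_zxy, points, values_c, values_a, pitch, n_samples):
    """Path integrals of wavenumber-per-speed and attenuation along straight
    rays from ``start_zxy`` (per-voxel or broadcastable) to each point.

    Returns (∫ ds / c_s  [mm·s/m... see caller], ∫ α ds) using midpoint
    sampling with nearest-voxel lookup (clamped at grid faces).
    """
    length = np.linalg.norm(points - start_zxy, axis=0)
    inv_c_int = np.zeros(length.shape)
    alpha_int = np.zeros(length.shape)
    step = length / n_samples
    shape = values_c.shape
    for m in range(n_samples):
        t = (m + 0.5) / n_samples
        q = start_zxy + t * (points - start_zxy)
        idx = []
        for ax in range(3):
            i = np.rint(q[ax] / pitch[ax]).astype(np.intp)
            np.clip(i, 0, shape[ax] - 1, out=i)
            idx.append(i)
        inv_c_int += step / values_c[tuple(idx)]
        alpha_int += step * values_a[tuple(idx)]
    return inv_c_int, alpha_int


def synthesize_wavefield(phantom: PhantomSpec,
                         sources: Sequence[SourceSpec],
                         ray_samples: int = 64) -> WaveField:
    """Superpose the phasor fields of one or more continuous sources.

    Heterogeneous phase accumulation uses straight-ray midpoint integration
    of the local wavenumber k = 2πf/c_s from the source (or the plane-wave
    entry plane) to each voxel.  Homogeneous phantoms take an exact closed
    form.

    Raises ``ValueError`` for an empty source list, mixed drive frequencies,
    or a point source coinciding with a voxel (singular spreading).
    """
    if len(sources) == 0:
        raise ValueError("at least one source is required")
    freqs = {s.frequency_hz for s in sources}
    if len(freqs) > 1:
        raise ValueError(f"all sources must share one drive frequency, got {sorted(freqs)}")
    f = freqs.pop()

    c_map = phantom.speed_map()
    a_map = phantom.attenuation_map()
    homogeneous = (np.ptp(c_map) == 0.0) and (np.ptp(a_map) == 0.0)
    pitch = phantom.voxel_pitch_mm
    zz, xx, yy = phantom._meshgrid()
    points = np.stack([zz, xx, yy])                    # (3, nz, nx, ny), mm

    total = np.zeros(phantom.grid_shape, dtype=complex)
    for src in sources:
        if src.kind == "plane":
            d = np.asarray(src.direction)[:, None, None, None]
            s = (points * d).sum(axis=0)               # signed distance along direction
            corners = np.array([[cz, cx, cy]
                                for cz in (zz.min(), zz.max())
                                for cx in (xx.min(), xx.max())
                                for cy in (yy.min(), yy.max())])
            s0 = float((corners @ np.asarray(src.direction)).min())
            length = s - s0                            # path inside the grid
            start = points - length * d
            spreading = np.ones_like(length)
        else:
            pos = np.asarray(src.position_mm)[:, None, None, None]
            length = np.linalg.norm(points - pos, axis=0)
            if length.min() < 1e-9:
                raise ValueError("point source coincides with a voxel (singular 1/sqrt(r) spreading)")
            start = np.broadcast_to(pos, points.shape)
            spreading = 1.0 / np.sqrt(length)          # A0 referenced at r = 1 mm

        if homogeneous:
            # k [rad/mm] = 2πf / (1000 · c_s[m/s])
            phase = src.phase_rad - 2.0 * np.pi * f / (1000.0 * phantom.background_c_s) * length
            decay = np.exp(-phantom.background_alpha * length)
        else:
            inv_c_int, alpha_int = _ray_integrals(start, points, c_map, a_map,
                                                  pitch, ray_samples)
            phase = src.phase_rad - 2.0 * np.pi * f / 1000.0 * inv_c_int
            decay = np.exp(-alpha_int)

        total += src.amplitude_um * spreading * decay * np.exp(1j * phase)

    return WaveField(phasor=total, pitch_mm=pitch, frequency_hz=f)


def synthesize_displacement_series(wave: WaveField,
                                   periods: int,
                                   samples_per_period: int = 6,
                                   noise: Optional[NoiseSpec] = None) -> DisplacementVolume:
    """Sample the wavefield into a displacement-versus-slow-time volume.

    The PRF is locked to ``samples_per_period`` × drive frequency (the
    acquisition contract that puts the drive tone on an exact FFT bin), and
    slices share a common trigger so the series is phase-coherent in 3D.
    """
    if periods < 2:
        raise ValueError("need at least 2 periods for usable FFT bin resolution")
    if samples_per_period < 3:
        raise ValueError("need at least 3 samples per period (drive-tone Nyquist)")

    f = wave.frequency_hz
    prf = samples_per_period * f
    t = np.arange(periods * samples_per_period) / prf
    omega_t = 2.0 * np.pi * f * t

    d = wave.amplitude[..., None] * np.cos(wave.phase[..., None] + omega_t)
    if noise is not None:
        for tone_f, tone_amp in noise.tones:
            d = d + tone_amp * np.sin(2.0 * np.pi * tone_f * t)
        if noise.sigma_um > 0:
            rng = np.random.default_rng(noise.seed)
            d = d + rng.normal(0.0, noise.sigma_um, size=d.shape)

    return DisplacementVolume(data=d, pitch_mm=wave.pitch_mm,
                              sample_rate_hz=prf, drive_frequency_hz=f)


def _sphere_mask(shape, pitch, center_mm, radius_mm) -> np.ndarray:
    z, x, y = axis_coordinates(shape, pitch)
    zz, xx, yy = np.meshgrid(z, x, y, indexing="ij")
    cz, cx, cy = center_mm
    return ((zz - cz) ** 2 + (xx - cx) ** 2 + (yy - cy) ** 2) <= radius_mm ** 2


def make_phantom(kind: str, **params):
    """Build a ready-made phantom scenario with ground truth and tumour mask.

    kind="homogeneous"
        Uniform medium.  Params: ``extent_mm`` (default (12, 12, 10)),
        ``pitch_mm``, ``c_s`` (default 4.0 m/s), ``alpha``.  Mask covers the
        whole grid.  Returns a ``PhantomSpec``.
    kind="inclusion"
        Stiff (or soft) sphere in a background.  Params: ``background_c_s``,
        ``inclusion_c_s``, ``radius_mm``, ``center_mm`` (default grid centre),
        plus extent/pitch/alpha.  Returns a ``PhantomSpec``.
    kind="treated-pair"
        Baseline and 24 h follow-up phantoms emulating a vascular-disrupting-
        agent response: a tumour sphere whose large central core softens by
        ``core_change_pct`` while a thin viable rim is unchanged.  Params:
        ``tumour_radius_mm`` (2.8), ``core_radius_mm`` (2.5), ``c_s`` (4.0),
        ``core_change_pct`` (−25), plus extent/pitch/alpha.  Returns
        ``(baseline, followup)``, both carrying the tumour mask.
    """
    extent = params.pop("extent_mm", (12.0, 12.0, 10.0))
    pitch = params.pop("pitch_mm", DEFAULT_PITCH_MM)
    shape = tuple(int(round(e / p)) for e, p in zip(extent, pitch))
    center = tuple(0.5 * (n - 1) * p for n, p in zip(shape, pitch))
    alpha = params.pop("alpha", 0.0)

    if kind == "homogeneous":
        c_s = params.pop("c_s", 4.0)
        _reject_unknown(params)
        if c_s <= 0:
            raise ValueError("shear speed must be positive")
        return PhantomSpec(grid_shape=shape, voxel_pitch_mm=pitch,
                           background_c_s=c_s, background_alpha=alpha,
                           mask=np.ones(shape, dtype=bool))

    if kind == "inclusion":
        bg = params.pop("background_c_s", 4.0)
        inc = params.pop("inclusion_c_s", 6.0)
        radius = params.pop("radius_mm", 2.0)
        c0 = params.pop("center_mm", center)
        _reject_unknown(params)
        if bg <= 0 or inc <= 0:
            raise ValueError("shear speeds must be positive")
        if radius >= min(extent) / 2:
            raise ValueError("inclusion radius must be smaller than the grid half-extent")
        sphere = Region("ellipsoid", c0, (radius, radius, radius), inc, alpha)
        return PhantomSpec(grid_shape=shape, voxel_pitch_mm=pitch,
                           background_c_s=bg, background_alpha=alpha,
                           regions=[sphere], mask=np.ones(shape, dtype=bool))

    if kind == "treated-pair":
        c_s = params.pop("c_s", 4.0)
        tumour_r = params.pop("tumour_radius_mm", 2.8)
        core_r = params.pop("core_radius_mm", 2.5)
        change = params.pop("core_change_pct", -25.0)
        _reject_unknown(params)
        if c_s <= 0:
            raise ValueError("shear speed must be positive")
        core_after = c_s * (1.0 + change / 100.0)
        if core_after <= 0:
            raise ValueError("core change leads to non-physical shear speed")
        if tumour_r >= min(extent) / 2:
            raise ValueError("tumour radius must be smaller than the grid half-extent")
        mask = _sphere_mask(shape, pitch, center, tumour_r)
        baseline = PhantomSpec(grid_shape=shape, voxel_pitch_mm=pitch,
                               background_c_s=c_s, background_alpha=alpha, mask=mask)
        core = Region("ellipsoid", center, (core_r, core_r, core_r), core_after, alpha)
        followup = PhantomSpec(grid_shape=shape, voxel_pitch_mm=pitch,
                               background_c_s=c_s, background_alpha=alpha,
                               regions=[core], mask=mask)
        return baseline, followup

    raise ValueError(f"unknown phantom kind {kind!r}")


def _reject_unknown(params: dict) -> None:
    if params:
        raise TypeError(f"unknown phantom parameters: {sorted(params)}")
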