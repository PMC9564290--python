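"""Local shear wave speed by directional kernel autocorrelation.

For each measurement point of a kernel grid laid over the tumour mask:

1.  *Direction detection* — the local wave vector is read per voxel from the
    spatial phase gradient of the drive-frequency phasor,
    ``k_w = −Im{conj(P)·∇P}`` (which carries an |P|² weight and needs no
    phase unwrapping); the amplitude²-weighted mean over the kernel, after
    normalisation, is the propagation direction (pointing away from the
    dominant source).  Incoherent kernels (weighted resultant length of the
    per-voxel directions < 0.5, e.g. at standing-wave nodes) are invalid.
2.  *Autocorrelation profile* — the complex phasor is cross-correlated with
    itself along ±direction at regular lag steps inside the cube kernel,
    sampled by trilinear interpolation.  The profile is the real part of
    the per-lag-normalised coefficient

        ρ(ℓ) = Re{ Σ P(x+ℓd̂)·conj(P(x)) } / √(Σ|P(x+ℓd̂)|² · Σ|P(x)|²),

    with sums over contributing pairs from both arms.  For a travelling
    plane wave ρ(ℓ) = cos(2πℓ/λ) exactly, for any kernel size, and
    exponential amplitude decay cancels in the normalisation.
3.  *Cosinusoidal fit* — least squares of B·cos(2πℓ/λ), B ∈ (0, 1], λ
    bounded by the physical speed range, initialised from a log-spaced grid
    search; c_s = λ·f and GoF = RMS fit residual.

Assembling every point yields the (m × n × p) speed map from which
tumour-level statistics are reduced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.optimize import least_squares

from .containers import WaveField

__all__ = [
    "KernelGrid",
    "SpeedMap",
    "CosinusoidFit",
    "build_kernel_grid",
    "detect_direction",
    "kernel_acf_profile",
    "fit_cosinusoid",
    "build_speed_map",
]

DEFAULT_KERNEL_MM = 2.0
DEFAULT_SPACING_MM = 0.5
DEFAULT_C_BOUNDS = (0.5, 15.0)      # m/s; generous margin around tumour ~4 m/s
MIN_COHERENCE = 0.5
MIN_PAIRS_PER_LAG = 8
MIN_FIT_SAMPLES = 6


@dataclass
class KernelGrid:
    """Lattice of measurement points (m × n × p) restricted to a tumour mask."""

    z_mm: np.ndarray                 # (m,)
    x_mm: np.ndarray                 # (n,)
    y_mm: np.ndarray                 # (p,)
    inside: np.ndarray               # (m, n, p) bool: point centre lies in mask
    kernel_mm: float
    spacing_mm: float

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.z_mm), len(self.x_mm), len(self.y_mm))

    @property
    def n_points(self) -> int:
        return int(self.inside.sum())

    def point_mm(self, i: int, j: int, k: int) -> tuple[float, float, float]:
        return (float(self.z_mm[i]), float(self.x_mm[j]), float(self.y_mm[k]))


@dataclass
class CosinusoidFit:
    wavelength_mm: float
    c_s: float                       # m/s, = wavelength·f (λ mm, f Hz, /1000)
    gof: float                       # RMS residual of the cosinusoidal fit
    amplitude: float                 # fitted B
    valid: bool


@dataclass
class SpeedMap:
    """Per-point shear wave speed, fit quality, direction and validity."""

    grid: KernelGrid
    frequency_hz: float
    c_s: np.ndarray                  # (m, n, p), m/s, NaN where invalid
    wavelength_mm: np.ndarray        # (m, n, p)
    gof: np.ndarray                  # (m, n, p)
    direction: np.ndarray            # (m, n, p, 3) unit vectors, NaN where invalid
    valid: np.ndarray                # (m, n, p) bool

    def valid_speeds(self) -> np.ndarray:
        return self.c_s[self.valid]

    def median_speed(self) -> float:
        v = self.valid_speeds()
        return float(np.median(v)) if v.size else float("nan")

    def valid_fraction(self) -> float:
        n = self.grid.n_points
        return float(self.valid.sum() / n) if n else 0.0

    def to_frame(self) -> pd.DataFrame:
        """Long table: one row per measurement point."""
        m, n, p = self.grid.shape
        ii, jj, kk = np.meshgrid(range(m), range(n), range(p), indexing="ij")
        return pd.DataFrame({
            "z_mm": self.grid.z_mm[ii.ravel()],
            "x_mm": self.grid.x_mm[jj.ravel()],
            "y_mm": self.grid.y_mm[kk.ravel()],
            "in_mask": self.grid.inside.ravel(),
            "c_s": self.c_s.ravel(),
            "wavelength_mm": self.wavelength_mm.ravel(),
            "gof": self.gof.ravel(),
            "valid": self.valid.ravel(),
            "frequency_hz": self.frequency_hz,
        })


def build_kernel_grid(mask: np.ndarray,
                      pitch_mm: tuple[float, float, float],
                      kernel_mm: float = DEFAULT_KERNEL_MM,
                      spacing_mm: float = DEFAULT_SPACING_MM) -> KernelGrid:
    """Lay a lattice of measurement points over the mask bounding box.

    Points are spaced ``spacing_mm`` apart, inset by half a kernel from the
    physical bounding box of the mask (so kernels sit inside it), and only
    points whose centre falls on a mask voxel are kept.  If the box is
    smaller than the kernel along an axis, a single centred point is used.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if spacing_mm <= 0 or kernel_mm <= 0:
        raise ValueError("kernel size and spacing must be positive")
    if spacing_mm > kernel_mm:
        raise ValueError("spacing must not exceed the kernel edge (gaps in coverage)")

    axes = []
    nz = np.nonzero(mask)
    for ax in range(3):
        lo = nz[ax].min() * pitch_mm[ax] - pitch_mm[ax] / 2.0   # physical bbox edges
        hi = nz[ax].max() * pitch_mm[ax] + pitch_mm[ax] / 2.0
        extent = hi - lo
        if extent >= kernel_mm:
            count = int(np.floor((extent - kernel_mm) / spacing_mm + 1e-9)) + 1
        else:
            count = 1
        span = (count - 1) * spacing_mm
        start = lo + (extent - span) / 2.0
        axes.append(start + spacing_mm * np.arange(count))

    zz, xx, yy = np.meshgrid(*axes, indexing="ij")
    inside = np.zeros(zz.shape, dtype=bool)
    idx = []
    for ax, coords in enumerate((zz, xx, yy)):
        i = np.rint(coords / pitch_mm[ax]).astype(np.intp)
        np.clip(i, 0, mask.shape[ax] - 1, out=i)
        idx.append(i)
    inside = mask[tuple(idx)]
    return KernelGrid(z_mm=axes[0], x_mm=axes[1], y_mm=axes[2],
                      inside=inside, kernel_mm=float(kernel_mm),
                      spacing_mm=float(spacing_mm))


def _kernel_slices(field: WaveField, point_mm, kernel_mm: float):
    """Voxel index slices of the cube kernel centred on a point."""
    slices = []
    for ax in range(3):
        pitch = field.pitch_mm[ax]
        half = kernel_mm / 2.0
        lo = int(np.ceil((point_mm[ax] - half) / pitch - 1e-9))
        hi = int(np.floor((point_mm[ax] + half) / pitch + 1e-9))
        lo = max(lo, 0)
        hi = min(hi, field.shape[ax] - 1)
        if hi < lo:
            raise ValueError("kernel lies outside the field grid")
        slices.append(slice(lo, hi + 1))
    return tuple(slices)


def _weighted_wavevector(field: WaveField):
    """Per-voxel |P|²-weighted wave vector −Im{conj(P)·∇P} and weights |P|²."""
    p = field.phasor
    grads = np.gradient(p, *field.pitch_mm, edge_order=1)
    kvec_w = np.stack([-np.imag(np.conj(p) * g) for g in grads])
    weight = np.abs(p) ** 2
    return kvec_w, weight


def _direction_from_kvec(kvec_w: np.ndarray, weight: np.ndarray,
                         min_coherence: float = MIN_COHERENCE) -> Optional[np.ndarray]:
    """Reduce per-voxel weighted wave vectors to one unit direction, or None."""
    total_w = weight.sum()
    if total_w <= 0:
        return None
    mean_vec = kvec_w.reshape(3, -1).sum(axis=1)
    norm = np.linalg.norm(mean_vec)
    if norm == 0:
        return None
    # coherence: weighted resultant length of the per-voxel unit directions
    mags = np.linalg.norm(kvec_w, axis=0)
    ok = mags > 0
    if not ok.any():
        return None
    units = kvec_w[:, ok] / mags[ok]
    w = weight[ok]
    resultant = np.linalg.norm((units * w).sum(axis=1)) / w.sum()
    if resultant < min_coherence:
        return None
    return mean_vec / norm


def detect_direction(field: WaveField, point_mm, kernel_mm: float = DEFAULT_KERNEL_MM,
                     min_coherence: float = MIN_COHERENCE) -> Optional[np.ndarray]:
    """Local propagation direction within a kernel, or None if undetectable.

    None is returned when the kernel holds fewer than 5³ voxels of nonzero
    amplitude or the per-voxel wave vectors are incoherent (weighted
    resultant length < ``min_coherence``), e.g. at standing-wave nodes.
    """
    sl = _kernel_slices(field, point_mm, kernel_mm)
    kvec_w, weight = _weighted_wavevector(field)
    kvec_w = kvec_w[(slice(None),) + sl]
    weight = weight[sl]
    if (weight > 0).sum() < 5 ** 3:
        return None
    return _direction_from_kvec(kvec_w, weight, min_coherence)


def _acf_lags(kernel_mm: float, pitch_mm) -> np.ndarray:
    """Lag sampling: steps of the finest pitch up to kernel − one pitch,
    halving the step until at least 8 samples exist (tiny kernels)."""
    step = float(min(pitch_mm))
    max_lag = kernel_mm - step
    while max_lag / step + 1 < 8 and step > 1e-6:
        step /= 2.0
        max_lag = kernel_mm - min(pitch_mm)
    n = int(np.floor(max_lag / step + 1e-9)) + 1
    return step * np.arange(n)


def kernel_acf_profile(field: WaveField, point_mm, kernel_mm: float,
                       direction: np.ndarray,
                       min_pairs: int = MIN_PAIRS_PER_LAG):
    """Directional autocorrelation profile of the phasor inside the kernel.

    Returns ``(lags_mm, profile)`` with ``profile[0] == 1``; the profile is
    truncated at the first lag with fewer than ``min_pairs`` contributing
    pairs (per arm pool).
    """
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if not np.isfinite(norm) or norm == 0:
        raise ValueError("direction must be a finite non-zero vector")
    direction = direction / norm

    sl = _kernel_slices(field, point_mm, kernel_mm)
    cube = field.phasor[sl]
    shape = np.array(cube.shape)
    pitch = np.array(field.pitch_mm)
    lags = _acf_lags(kernel_mm, field.pitch_mm)

    base_idx = np.stack(np.meshgrid(*[np.arange(n, dtype=float) for n in shape],
                                    indexing="ij")).reshape(3, -1)   # (3, nvox)
    step_vox = (direction / pitch)[:, None]                          # lag of 1 mm in voxels

    nums = np.zeros(len(lags))
    e_shift = np.zeros(len(lags))
    e_base = np.zeros(len(lags))
    counts = np.zeros(len(lags), dtype=int)

    cube_re = cube.real
    cube_im = cube.imag
    base_vals = cube.reshape(-1)
    hi = (shape - 1)[:, None]
    for m, lag in enumerate(lags):
        pooled_num = 0.0 + 0.0j
        pooled_es = 0.0
        pooled_eb = 0.0
        pooled_n = 0
        for sign in ((1.0,) if lag == 0 else (1.0, -1.0)):
            coords = base_idx + sign * lag * step_vox
            ok = np.all((coords >= 0) & (coords <= hi), axis=0)
            if not ok.any():
                continue
            c = coords[:, ok]
            shifted = (map_coordinates(cube_re, c, order=1)
                       + 1j * map_coordinates(cube_im, c, order=1))
            base = base_vals[ok]
            pooled_num += np.sum(shifted * np.conj(base))
            pooled_es += np.sum(np.abs(shifted) ** 2)
            pooled_eb += np.sum(np.abs(base) ** 2)
            pooled_n += int(ok.sum())
        nums[m] = pooled_num.real
        e_shift[m] = pooled_es
        e_base[m] = pooled_eb
        counts[m] = pooled_n

    keep = len(lags)
    for m in range(len(lags)):
        if counts[m] < min_pairs or e_shift[m] <= 0 or e_base[m] <= 0:
            keep = m
            break
    if keep == 0:
        raise ValueError("kernel has no usable autocorrelation pairs")
    lags = lags[:keep]
    profile = nums[:keep] / np.sqrt(e_shift[:keep] * e_base[:keep])
    return lags, profile


def fit_cosinusoid(lags_mm: np.ndarray, profile: np.ndarray, frequency_hz: float,
                   c_bounds: tuple[float, float] = DEFAULT_C_BOUNDS) -> CosinusoidFit:
    """Fit B·cos(2π·lag/λ) to an autocorrelation profile.

    λ is constrained to [c_min/f, c_max/f] and B to (0, 1]; the fit is
    initialised from a 50-candidate log-spaced grid search over λ and
    refined by bounded least squares.  A fit pinned at a λ bound (or a
    failed refinement) is flagged invalid.  GoF is the RMS residual.
    """
    lags_mm = np.asarray(lags_mm, dtype=float)
    profile = np.asarray(profile, dtype=float)
    if len(lags_mm) < MIN_FIT_SAMPLES:
        raise ValueError(f"need at least {MIN_FIT_SAMPLES} lag samples, got {len(lags_mm)}")
    if len(lags_mm) != len(profile):
        raise ValueError("lags and profile must have equal length")

    lam_lo = c_bounds[0] / frequency_hz * 1000.0     # mm
    lam_hi = c_bounds[1] / frequency_hz * 1000.0
    b_lo = 1e-6

    candidates = np.geomspace(lam_lo, lam_hi, 50)
    best = None
    for lam in candidates:
        basis = np.cos(2.0 * np.pi * lags_mm / lam)
        denom = basis @ basis
        b = float(np.clip((profile @ basis) / denom, b_lo, 1.0)) if denom > 0 else b_lo
        rss = float(np.sum((profile - b * basis) ** 2))
        if best is None or rss < best[0]:
            best = (rss, b, lam)

    def residuals(theta):
        b, lam = theta
        return b * np.cos(2.0 * np.pi * lags_mm / lam) - profile

    x0 = np.clip([best[1], best[2]], [b_lo, lam_lo], [1.0, lam_hi])
    result = least_squares(residuals, x0=x0, bounds=([b_lo, lam_lo], [1.0, lam_hi]),
                           xtol=1e-14, ftol=1e-14, gtol=1e-14)
    b_fit, lam_fit = result.x
    gof = float(np.sqrt(np.mean(result.fun ** 2)))
    pinned = (lam_fit <= lam_lo * (1 + 1e-3)) or (lam_fit >= lam_hi * (1 - 1e-3))
    valid = bool(result.success) and not pinned
    return CosinusoidFit(wavelength_mm=float(lam_fit),
                         c_s=float(lam_fit * frequency_hz / 1000.0),
                         gof=gof, amplitude=float(b_fit), valid=valid)


def build_speed_map(field: WaveField, grid: KernelGrid,
                    c_bounds: tuple[float, float] = DEFAULT_C_BOUNDS,
                    min_coherence: float = MIN_COHERENCE) -> SpeedMap:
    """Run direction detection, autocorrelation and cosinusoidal fitting at
    every in-mask grid point; deterministic given its inputs.

    Records a warning if more than half the points come out invalid.
    """
    shape = grid.shape
    c_s = np.full(shape, np.nan)
    lam = np.full(shape, np.nan)
    gof = np.full(shape, np.nan)
    direction = np.full(shape + (3,), np.nan)
    valid = np.zeros(shape, dtype=bool)

    kvec_w, weight = _weighted_wavevector(field)

    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if not grid.inside[i, j, k]:
                    continue
                point = grid.point_mm(i, j, k)
                try:
                    sl = _kernel_slices(field, point, grid.kernel_mm)
                except ValueError:
                    continue
                w_cube = weight[sl]
                if (w_cube > 0).sum() < 5 ** 3:
                    continue
                d = _direction_from_kvec(kvec_w[(slice(None),) + sl], w_cube,
                                         min_coherence)
                if d is None:
                    continue
                try:
                    lags, profile = kernel_acf_profile(field, point, grid.kernel_mm, d)
                    fit = fit_cosinusoid(lags, profile, field.frequency_hz, c_bounds)
                except ValueError:
                    continue
                c_s[i, j, k] = fit.c_s
                lam[i, j, k] = fit.wavelength_mm
                gof[i, j, k] = fit.gof
                direction[i, j, k] = d
                valid[i, j, k] = fit.valid

    n_points = grid.n_points
    if n_points and valid.sum() < 0.5 * n_points:
        warnings.warn(f"speed map: only {valid.sum()}/{n_points} measurement points "
                      "are valid", stacklevel=2)
    return SpeedMap(grid=grid, frequency_hz=field.frequency_hz, c_s=c_s,
                    wavelength_mm=lam, gof=gof, direction=direction, valid=valid)
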