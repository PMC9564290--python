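# Methods

This note records the models, numerical choices and limitations behind
`vswe3d`, in the spirit of a methods appendix: what each stage assumes, which
defaults matter, and what a passing test does and does not establish.

## Coordinate and phasor conventions

Volumes are indexed `(z, x, y)` — axial, lateral, elevational — with
voxel-centre coordinates in mm and the slow-time (pulse-to-pulse) axis last.
The default pitch is 0.1 mm in z/x and 0.2 mm in y, matching a stepped-probe
acquisition. The drive-frequency phasor `P` is defined by
`d(t) = Re{P·exp(+i2πft)}`; spectra use the standard forward-DFT kernel
`exp(−i2πkt/N)`, so a travelling wave away from its source is
`P(r) = A(r)·exp(i(φ₀ − k·r))` and `d = A·sin(2πft)` has phase −π/2. This
convention is applied once, here, and everywhere else follows from it.

## Wave-field simulator

The simulator's purpose is to exercise the *measurement* chain, not to solve
elastodynamics. Each source contributes

    P(r) = A₀ · g(r) · exp(−∫α ds) · exp(i(φ₀ − ∫k ds)),  k = 2πf/c_s,

integrated along the straight ray from the source (or plane-wave entry
plane) to the voxel by midpoint sampling with nearest-voxel material lookup
(64 samples; exact closed form in homogeneous media). Geometric spreading is
`1/√r` for point sources — the cylindrical-like decay near a rod contactor,
with amplitude referenced at r = 1 mm — and 1 for plane waves, which exist
for analytic tests. Superposition is linear, so two-source interference
(including standing-wave nodes, where the direction detector correctly gives
up) is represented.

Not represented: refraction, diffraction, reflections at boundaries and
mode conversion. Consequently a heterogeneous phantom has exact *local*
wavelengths but physically simplified fields near inclusion boundaries
(sharp shadow edges instead of diffracted transitions). A green recovery
test on the inclusion phantom therefore establishes that the estimator
reads local wavelength correctly, not that it would be unbiased under full
wave physics. Whether a point or line/plane source best matches a real
contactor is left open; both are provided.

Displacement sampling locks the PRF to `samples_per_period × f` (default 6)
over whole periods (default 10, minimum 2), with a common trigger across
slices — this is the contract that puts the drive tone on an exact FFT bin,
and misaligned inputs are rejected rather than windowed. Displacement-domain
noise (white σ per sample, optional interfering tones) is seeded and added
after wave synthesis.

## Echo model and displacement estimator

IQ is defined directly on the reconstructed voxel grid (no beamforming,
focusing or element geometry): seeded Rayleigh-amplitude/uniform-phase
speckle, constant over slow time, phase-modulated by `(4πf_c/c_us)·d` with
`f_c = 18.5 MHz` and `c_us = 1540 m/s` (6.624 µm per radian), plus complex
white noise at a stated SNR. Displacement steps with |Δφ| ≥ π raise an
aliasing warning; at 10 µm drive amplitude the modulation stays well inside
±π.

The estimator is the lag-one slow-time autocorrelation: complex products
`IQ(j+1)·conj(IQ(j))` (speckle phase cancels), coherently averaged over a
0.5 mm axial window — far below the 3–11 mm shear wavelengths mapped here,
so the wave is not blurred, while noise variance drops roughly with window
length. Angles are scaled to µm, accumulated, and the cumulative series is
demeaned; integration drift is a DC/low-frequency artefact that never
reaches the drive bin. Voxels with zero IQ magnitude are flagged invalid.

## Conformance

`C(%) = 100·|S_f|²/Σ|S_i|²` with the denominator summed over the one-sided
spectrum, bins 1…N/2. DC is excluded: the series is demeaned upstream and
only oscillatory energy counts as vibrational. All-zero spectra are
undefined (NaN + flag), not 0. Tumour-level C is reported as the spatial
median within the mask, the same reduction used for c_s.

## Speed estimation

**Kernel grid.** Measurement points are laid `spacing` apart (≤ kernel
edge), inset by half a kernel from the physical bounding box of the mask,
keeping points whose centre voxel is masked; a box smaller than the kernel
gets one centred point. A 10 mm cube with 2 mm kernels at 0.5 mm spacing
gives 17 points per axis.

**Direction.** The per-voxel wave vector is `−Im{conj(P)∇P}` (an
|P|²-weighted phase gradient needing no unwrapping; central differences at
the configured pitches). Its kernel sum, normalised, is the direction —
pointing away from the dominant source. Validity requires ≥ 5³ nonzero
voxels and a weighted resultant length ≥ 0.5 of the per-voxel directions;
standing-wave nodes and noise-dominated kernels fail this coherence gate.

**Autocorrelation.** The profile is the real part of the per-lag-normalised
complex phasor cross-correlation along ±direction (both arms pooled),

    ρ(ℓ) = Re{Σ P(x+ℓd̂)·conj(P(x))} / √(Σ|P(x+ℓd̂)|²·Σ|P(x)|²),

sampled by trilinear interpolation inside the cube at lag steps of the
finest pitch (halved until ≥ 8 samples exist, which is what makes 0.5 mm
kernels usable at 0.1 mm pitch), truncated where fewer than 8 pairs
contribute. Two properties motivated this choice over autocorrelating the
real wave image `Re{P}` normalised by its zero-lag value: (i) for a
travelling plane wave ρ(ℓ) = cos(2πℓ/λ) *exactly, under any window*,
whereas the real-image ACF carries a finite-window cross term of order
1/(kL) — several percent for a 2 mm kernel at these wavelengths — that
biases the fit precisely when the kernel is small relative to λ; (ii) the
per-lag energy normalisation cancels exponential amplitude decay
(attenuation, near-exponential spreading) exactly, so no decay envelope is
needed in the fit model. For a plane wave the two formulations agree in
periodicity; ours is the one for which the cosine model is exact.

**Fit.** Bounded least squares of `B·cos(2πℓ/λ)`, `B ∈ (0, 1]`,
`λ ∈ [c_min, c_max]/f` with speed bounds 0.5–15 m/s — wide margin around
the ~4 m/s tumour range, preventing degenerate λ → ∞ fits — initialised
from a 50-candidate log-spaced grid search. `c_s = λf`; GoF is the RMS
residual; a fit pinned at a λ bound (within 0.1%) or failing to converge is
flagged invalid but retained in the map. Low-Conformance points are *not*
excluded by default; validity gating beyond the above is left to the user.

## Summary statistics

The tumour statistic is the spatial **median** of c_s over valid points
(means are carried as diagnostics only). The dispersion slope is the OLS
slope of median c_s versus frequency. `CV_WS(%) = 100·√(Σ(Δ/m)²/2n)` over
test–retest pairs. Young's modulus uses `E = 3ρc_s²` with ρ fixed at
1000 kg/m³ — the incompressible, purely elastic idealisation under which
4 m/s ↔ 48 kPa. Hypothesis testing is deliberately out of scope; summary
tables are exported for external statistics.

## Pipeline and reproducibility

`RunConfig` (YAML/JSON-serialisable) fully determines a run: per-stage
seeds are derived from the single run seed via `SeedSequence` spawn keys,
artefacts are stamped with the SHA-256 of the canonical config JSON, and
identical config + seed reproduces outputs byte-for-byte. Stage failures
raise errors naming the stage. Containers round-trip through HDF5 (primary)
or NPZ, masks through NIfTI or multipage TIFF.

## Default test world

End-to-end tests run a point source 5 mm outside an 8×8×6 mm grid, 10 µm
amplitude, 0.05 Np/mm attenuation, IQ SNR 30 dB, 10 periods at 6
samples/period, 2 mm kernels; the treated-pair phantom is a 2.8 mm-radius
tumour sphere whose 2.5 mm core softens by 25% under an unchanged thin
viable rim — the characteristic central-necrosis response to a
vascular-disrupting agent. Grid sizes are kept at desk scale (minutes on
one CPU); they establish estimator correctness and noise robustness, not
in-vivo effect sizes, which additionally involve physiology (respiratory
motion, real speckle statistics, heterogeneous attenuation) that the
simulator does not emulate.

## Known limitations

- Straight-ray propagation: no diffraction/refraction; inclusion-boundary
  fields are idealised.
- No beamforming or point-spread-function model; IQ lives on the voxel grid.
- The cosinusoid model fits no decay envelope; strongly non-exponential
  amplitude profiles within a kernel (e.g. across a node) reduce B and
  inflate GoF rather than bias λ gracefully.
- Oblique propagation relies on trilinear interpolation (≲2% speed error);
  axis-aligned propagation is exact.
- Dispersion is represented only through per-frequency phantoms; no
  intrinsic viscoelastic material model.
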