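"""Recover shear wave speed from a noiseless plane wave.

Builds a homogeneous 4 m/s phantom carrying a 700 Hz plane shear wave,
maps speed with 2 mm kernels, and compares every point with the truth.
"""

import numpy as np

import vswe3d as v

phantom = v.make_phantom("homogeneous", extent_mm=(6.0, 6.0, 6.0),
                         pitch_mm=(0.1, 0.1, 0.1), c_s=4.0)
source = v.SourceSpec(frequency_hz=700.0, kind="plane", direction=(0, 1, 0),
                      amplitude_um=10.0)
field = v.synthesize_wavefield(phantom, [source])

mask = np.zeros(phantom.grid_shape, bool)
mask[10:50, 10:50, 10:50] = True          # keep kernels inside the grid
grid = v.build_kernel_grid(mask, phantom.voxel_pitch_mm,
                           kernel_mm=2.0, spacing_mm=1.0)
speed_map = v.build_speed_map(field, grid)

speeds = speed_map.valid_speeds()
print(f"measurement points : {grid.n_points}")
print(f"median c_s         : {speed_map.median_speed():.4f} m/s  (truth 4.0)")
print(f"worst-case error   : {np.abs(speeds - 4.0).max() / 4.0 * 100:.4f} %")
print(f"median GoF         : {np.median(speed_map.gof[speed_map.valid]):.2e}")
# The wavelength at 700 Hz in 4 m/s tissue is 5.71 mm; the 2 mm kernel
# still recovers it because the cosinusoid fit constrains the model.
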