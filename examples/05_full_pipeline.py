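"""Run the configured multi-frequency pipeline and export artefacts.

One RunConfig drives the whole chain for three vibration frequencies; the
run writes phasor/conformance/speed artefacts, a summary table and a
provenance log (config hash, validity fractions) to an output directory,
and reports the dispersion slope of c_s versus frequency.
"""

import tempfile
from pathlib import Path

import vswe3d as v

config = v.RunConfig(
    phantom={"kind": "homogeneous",
             "params": {"extent_mm": [5.0, 5.0, 4.0],
                        "pitch_mm": [0.1, 0.1, 0.2], "c_s": 4.0}},
    sources=[{"kind": "plane", "direction": [0.0, 1.0, 0.0],
              "amplitude_um": 10.0}],
    frequencies_hz=[700.0, 1000.0, 1200.0],
    echo={"enabled": False},        # analyse noiseless displacement directly
    noise_sigma_um=0.2,
    kernel_mm=2.0, spacing_mm=1.0, seed=7,
)

out = Path(tempfile.mkdtemp(prefix="vswe3d_demo_"))
result = v.run_pipeline(config, out_dir=out)

print(result.summary[["frequency_hz", "median_c_s", "n_valid",
                      "median_conformance"]].to_string(index=False))
print(f"dispersion slope : {result.slope:+.2e} m/s per Hz "
      "(≈0: the phantom is purely elastic)")
print(f"artefacts in     : {out}")
for artefact in sorted(p.name for p in out.iterdir()):
    print(f"  {artefact}")
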