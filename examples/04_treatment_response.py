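"""Detect a treatment-induced softening in a tumour phantom.

A baseline tumour (4 m/s sphere) and its 24 h follow-up, whose large
central core softened by 25% (emulating drug-induced necrosis with a thin
viable rim), are pushed through the full IQ-level chain at 30 dB SNR; the
relative change in tumour-median c_s recovers the softening.
"""

import vswe3d as v

common = dict(
    sources=[{"kind": "point", "position_mm": [4.0, -5.0, 3.0],
              "amplitude_um": 10.0}],
    frequencies_hz=[700.0],
    echo={"enabled": True, "snr_db": 30.0},
    kernel_mm=2.0, spacing_mm=0.5,
)
params = {"extent_mm": [8.0, 8.0, 6.0], "pitch_mm": [0.1, 0.1, 0.2],
          "c_s": 4.0, "tumour_radius_mm": 2.8, "core_radius_mm": 2.5,
          "core_change_pct": -25.0, "alpha": 0.05}

medians = {}
for member, seed in (("baseline", 21), ("followup", 22)):
    cfg = v.RunConfig(phantom={"kind": "treated-pair", "params": params,
                               "member": member}, seed=seed, **common)
    record = v.run_pipeline(cfg).records[0]
    medians[member] = record.median_c_s
    print(f"{member:9s}: median c_s {record.median_c_s:.3f} m/s "
          f"({record.n_valid} points, median C {record.median_conformance:.1f}%)")

delta = v.relative_change(medians["baseline"], medians["followup"])
print(f"relative change Δc_s : {delta:+.1f} %  "
      "(core truth −25%, damped by the unchanged rim)")
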