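"""RMSSD activation tables, ROI contrasts, and hemispheric laterality.

Runs the preprocessing chain (detrend, 0.05-0.15 Hz band-pass, cycle
averaging, phase masking) on the cohort written by 02_simulate_cohort.py and
summarizes where the injected scene-storage effect shows up.
"""

from pathlib import Path

import hopfec as h

cohort = Path("scratch/example_cohort")
if not (cohort / "manifest.json").exists():
    raise SystemExit("run examples/02_simulate_cohort.py first")

scheme = h.default_scheme().subset(
    ["V1", "V2", "VMV1", "VMV2", "PHA1", "PHA2", "44", "45"])
roi = h.ROISet("scene_demo", ("VMV1", "VMV2", "PHA1", "PHA2"))

tables = {(task, phase): h.compute_activation(cohort, task, phase)
          for task in ("object_location", "word_pair")
          for phase in ("storage", "recall")}

print("mean ROI activation (RMSSD, arbitrary units) per condition:")
for (task, phase), table in tables.items():
    m = h.roi_mean(table, roi, scheme).mean()
    print(f"  {task:<16} {phase:<8} {m:.5f}")
print("The object_location/storage cell is elevated: that is the injected effect.")

res = h.paired_t(h.roi_mean(tables[("object_location", "storage")], roi, scheme),
                 h.roi_mean(tables[("word_pair", "storage")], roi, scheme))
print(f"paired t-test, scene ROI, object-location vs word-pair storage: "
      f"t = {res.t:.2f}, df = {res.df}, p = {res.p:.3g}")

lat, grand = h.laterality(tables[("object_location", "storage")], scheme)
print(f"grand-mean activation: {grand:.5f}")
print("mean R-L laterality per region (positive = right-dominant):")
print(lat.mean(axis=0).round(6).to_string())
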