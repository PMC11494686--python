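"""Build the 550-s episodic-memory block design and inspect its sampling.

Each task acquisition is 10 s of fixation followed by three cycles of
[80-s encoding block | 10-s counting baseline | 80-s retrieval block |
10-s counting baseline], sampled as 696 volumes at TR = 0.8 s.
"""

from hopfec import AcquisitionParams, build_task_design, design_to_events, phase_mask

design = build_task_design("object_location")
acq = AcquisitionParams()  # TR 0.8 s, 696 samples

print(f"task: {design.task}")
print(f"total duration: {design.total_duration:.0f} s "
      f"({acq.n_samples} samples at TR {acq.tr} s)")
events = design_to_events(design)
print(f"{len(events)} events; trials per condition:")
print(events.groupby("trial_type").size().to_string())

for phase in ("storage", "recall", "baseline", "fixation"):
    n = int(phase_mask(design, acq, phase).sum())
    print(f"  {phase:<9} {n:4d} samples")
print("Remaining samples past 550 s are prompt-time padding and belong to no phase.")
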