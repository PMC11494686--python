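"""Block-design episodic-memory task timelines and sample-level phase masks.

The default design is a 550-s acquisition: 10 s of fixation followed by three
identical 180-s cycles, each consisting of an 80-s encoding (storage) block of
eight 10-s trials (5-s image + 5-s blank), a 10-s counting-backwards baseline,
an 80-s retrieval (recall) block of eight trials, and another 10-s baseline.
Sampled at TR = 0.8 s the acquisition holds 696 volumes; samples beyond 550 s
(prompt time) are treated as padding and belong to no phase.

Because 10 s is not an integer number of TRs, events and samples do not share
boundaries.  A sample is assigned to an event iff its acquisition midpoint
time falls inside the event; this midpoint rule is deterministic and makes the
three cycles congruent in samples (225 samples each).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TASKS = ("object_location", "reward_location", "word_pair")

CONDITIONS = (
    "fixation",
    "encoding_image",
    "encoding_blank",
    "baseline_count",
    "retrieval_image",
    "retrieval_blank",
)

#: Analysis phases mapped onto event conditions.  Storage and recall span the
#: blank screens inside their blocks: the 0.1-Hz rise-and-fall of the response
#: extends across them.
PHASES = {
    "storage": ("encoding_image", "encoding_blank"),
    "recall": ("retrieval_image", "retrieval_blank"),
    "baseline": ("baseline_count",),
    "fixation": ("fixation",),
}

FIXATION_S = 10.0
IMAGE_S = 5.0
BLANK_S = 5.0
TRIALS_PER_BLOCK = 8
BASELINE_S = 10.0
N_CYCLES = 3


@dataclass(frozen=True)
class TrialEvent:
    onset: float            # seconds from acquisition start
    duration: float         # seconds
    condition: str
    cycle: int              # 1..3 (0 for fixation)
    trial: int              # ordinal within block (0 for non-trial events)


@dataclass(frozen=True)
class RunDesign:
    task: str
    events: tuple[TrialEvent, ...]
    total_duration: float

    @property
    def cycle_duration(self) -> float:
        return (self.total_duration - FIXATION_S) / N_CYCLES

    def cycle_start(self, cycle: int) -> float:
        return FIXATION_S + (cycle - 1) * self.cycle_duration


@dataclass(frozen=True)
class AcquisitionParams:
    """Sampling grid of one acquisition: TR in seconds and volume count."""

    tr: float = 0.8
    n_samples: int = 696

    def __post_init__(self):
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")

    @property
    def duration(self) -> float:
        return self.tr * self.n_samples

    def midpoints(self) -> np.ndarray:
        """Acquisition midpoint time of every sample."""
        return (np.arange(self.n_samples) + 0.5) * self.tr


def build_task_design(task: str) -> RunDesign:
    """The fixed 550-s design template for one of the three memory tasks."""
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    events: list[TrialEvent] = [TrialEvent(0.0, FIXATION_S, "fixation", 0, 0)]
    t = FIXATION_S
    for cycle in range(1, N_CYCLES + 1):
        for block, prefix in (("encoding", "encoding"), ("retrieval", "retrieval")):
            for trial in range(1, TRIALS_PER_BLOCK + 1):
                events.append(TrialEvent(t, IMAGE_S, f"{prefix}_image", cycle, trial))
                t += IMAGE_S
                events.append(TrialEvent(t, BLANK_S, f"{prefix}_blank", cycle, trial))
                t += BLANK_S
            events.append(TrialEvent(t, BASELINE_S, "baseline_count", cycle, 0))
            t += BASELINE_S
    return RunDesign(task=task, events=tuple(events), total_duration=t)


def phase_mask(design: RunDesign, acq: AcquisitionParams, phase: str) -> np.ndarray:
    """Boolean per-sample mask: midpoint of the sample falls in a phase event."""
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}; expected one of {sorted(PHASES)}")
    if acq.duration < design.total_duration:
        raise ValueError("acquisition does not cover the design duration")
    conditions = set(PHASES[phase])
    mid = acq.midpoints()
    mask = np.zeros(acq.n_samples, dtype=bool)
    for ev in design.events:
        if ev.condition in conditions:
            mask |= (mid >= ev.onset) & (mid < ev.onset + ev.duration)
    return mask


def condition_mask(design: RunDesign, acq: AcquisitionParams,
                   conditions: tuple[str, ...], cycle: int | None = None) -> np.ndarray:
    """Mask of samples whose midpoint lies in any listed condition (one cycle or all)."""
    mid = acq.midpoints()
    mask = np.zeros(acq.n_samples, dtype=bool)
    for ev in design.events:
        if ev.condition in conditions and (cycle is None or ev.cycle == cycle):
            mask |= (mid >= ev.onset) & (mid < ev.onset + ev.duration)
    return mask


def cycle_sample_slices(design: RunDesign, acq: AcquisitionParams) -> list[slice]:
    """Per-cycle sample index ranges (midpoint rule); all cycles equal length.

    Raises if the cycles do not hold the same number of samples, which for the
    default design they do (225 samples of 0.8 s per 180-s cycle).
    """
    mid = acq.midpoints()
    slices = []
    for cycle in range(1, N_CYCLES + 1):
        lo = design.cycle_start(cycle)
        hi = lo + design.cycle_duration
        inside = np.flatnonzero((mid >= lo) & (mid < hi))
        if inside.size == 0:
            raise ValueError(f"cycle {cycle} covers no samples")
        if inside[-1] - inside[0] + 1 != inside.size:
            raise ValueError(f"cycle {cycle} samples are not contiguous")
        slices.append(slice(int(inside[0]), int(inside[-1]) + 1))
    lengths = {s.stop - s.start for s in slices}
    if len(lengths) != 1:
        raise ValueError(f"cycles have unequal sample counts: {sorted(lengths)}")
    return slices


def cycle_phase_mask(design: RunDesign, acq: AcquisitionParams, phase: str) -> np.ndarray:
    """Phase mask relative to one cycle segment, valid for every cycle.

    The cycles are congruent under the midpoint rule, so the mask computed in
    cycle 1 transfers to the cycle-averaged template; congruence is verified.
    """
    slices = cycle_sample_slices(design, acq)
    full = phase_mask(design, acq, phase)
    rel = full[slices[0]]
    for s in slices[1:]:
        if not np.array_equal(full[s], rel):
            raise ValueError("phase masks are not congruent across cycles")
    return rel


def design_to_events(design: RunDesign) -> pd.DataFrame:
    """BIDS-style events table (onset, duration, trial_type, cycle, trial)."""
    return pd.DataFrame(
        {"onset": [e.onset for e in design.events],
         "duration": [e.duration for e in design.events],
         "trial_type": [e.condition for e in design.events],
         "cycle": [e.cycle for e in design.events],
         "trial": [e.trial for e in design.events]}
    )


def write_events_tsv(design: RunDesign, path) -> None:
    design_to_events(design).to_csv(path, sep="\t", index=False)
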