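"""RMSSD activation tables, hemisphere means, and right-minus-left laterality.

Activation of a region in a task phase is the root mean square successive
difference (RMSSD) of its preprocessed signal: sqrt(mean((x[t+1]-x[t])^2)).
For a block paradigm whose response rises and falls every 10 s, successive
differences are dominated by the paradigm-locked 0.1-Hz component, so RMSSD
tracks task engagement while being insensitive to slow drift.  The full chain
per participant and region is: detrend -> band-pass (activation band) ->
average the three task cycles -> mask the phase samples -> RMSSD.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import AcquisitionParams, RunDesign, build_task_design, cycle_phase_mask
from .parcellation import ParcellationScheme
from .preprocess import (ACTIVATION_BAND, BandpassSpec, TimeseriesRun,
                         average_cycles, bandpass, detrend_linear)
from .synth import load_manifest, load_run


@dataclass
class ActivationTable:
    """Participant x region RMSSD values for one task and phase."""

    values: pd.DataFrame        # index = participant ids, columns = full region labels
    task: str
    phase: str

    def __post_init__(self):
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("non-finite activation values")
        if (arr < 0).any():
            raise ValueError("RMSSD activations must be nonnegative")


def rmssd(series: np.ndarray) -> float:
    """Root mean square successive difference of a 1-D sample vector."""
    series = np.asarray(series, dtype=float).ravel()
    if series.size < 2:
        raise ValueError("RMSSD needs at least 2 samples")
    return float(np.sqrt(np.mean(np.diff(series) ** 2)))


def activation_from_run(ts: TimeseriesRun, design: RunDesign, phase: str,
                        band: BandpassSpec = ACTIVATION_BAND) -> np.ndarray:
    """Per-region RMSSD of one run for one phase (storage or recall)."""
    acq = AcquisitionParams(tr=ts.tr, n_samples=ts.n_samples)
    prepped = average_cycles(bandpass(detrend_linear(ts), band), design)
    mask = cycle_phase_mask(design, acq, phase)
    segment = prepped.values[mask]
    return np.apply_along_axis(rmssd, 0, segment)


def compute_activation(cohort_dir: str | Path, task: str, phase: str,
                       band: BandpassSpec = ACTIVATION_BAND) -> ActivationTable:
    """Activation table for every participant of a cohort, one task and phase."""
    manifest = load_manifest(cohort_dir)
    design = build_task_design(task)
    participants = [f"sub-{i + 1:02d}" for i in range(manifest["n_participants"])]
    rows = []
    for p in participants:
        ts = load_run(cohort_dir, p, task)
        rows.append(activation_from_run(ts, design, phase, band))
    values = pd.DataFrame(np.vstack(rows), index=participants,
                          columns=manifest["region_labels"])
    return ActivationTable(values=values, task=task, phase=phase)


def hemisphere_mean(table: ActivationTable, scheme: ParcellationScheme) -> pd.DataFrame:
    """Mean of the left and right member of every region pair, per participant."""
    cols = table.values.to_numpy(dtype=float)
    out = {}
    for lab, iL, iR in scheme.pairs():
        out[lab] = 0.5 * (cols[:, iL] + cols[:, iR])
    return pd.DataFrame(out, index=table.values.index)


def laterality(table: ActivationTable, scheme: ParcellationScheme) -> tuple[pd.DataFrame, float]:
    """Right-minus-left activation per region pair, plus the grand-mean activation.

    The grand mean (over all participants and regions of the input table) is
    the baseline around which laterality is conventionally displayed; the
    returned differences themselves are plain R - L.
    """
    cols = table.values.to_numpy(dtype=float)
    out = {}
    for lab, iL, iR in scheme.pairs():
        out[lab] = cols[:, iR] - cols[:, iL]
    grand_mean = float(cols.mean())
    return pd.DataFrame(out, index=table.values.index), grand_mean
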