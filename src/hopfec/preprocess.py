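"""Timeseries preprocessing: region averaging, detrending, band-pass, cycle averaging.

Two frequency bands are used downstream.  The activation band (default
0.05–0.15 Hz) brackets the 0.1-Hz fundamental of the 10-s trial paradigm and
feeds the RMSSD activation measure; the connectivity band (0.008–0.08 Hz) is
the conventional slow-BOLD band used for Pearson functional connectivity.
Both are realized as second-order Butterworth band-passes applied forward and
backward (zero phase), so that event-locked phase masks stay aligned with the
filtered signal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .design import AcquisitionParams, RunDesign, cycle_sample_slices


@dataclass(frozen=True)
class BandpassSpec:
    """Butterworth band-pass: corner frequencies in Hz, order, zero-phase flag."""

    low: float
    high: float
    order: int = 2
    zero_phase: bool = True

    def validate(self, tr: float) -> None:
        nyquist = 0.5 / tr
        if not (0 <= self.low < self.high):
            raise ValueError(f"invalid band: low={self.low}, high={self.high}")
        if self.high >= nyquist:
            raise ValueError(f"band high {self.high} Hz >= Nyquist {nyquist} Hz")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


#: Band for the RMSSD activation measure (paradigm fundamental 0.1 Hz).
ACTIVATION_BAND = BandpassSpec(low=0.05, high=0.15)
#: Band for functional connectivity.
FC_BAND = BandpassSpec(low=0.008, high=0.08)


@dataclass
class TimeseriesRun:
    """One time x region matrix with its sampling interval and labels."""

    values: np.ndarray          # (n_samples, n_regions)
    tr: float
    region_labels: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (time x region)")
        if self.values.shape[1] != len(self.region_labels):
            raise ValueError("label count does not match column count")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite values in timeseries")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def average_within_regions(vertex_values: np.ndarray,
                           vertex_to_region: Sequence[str],
                           region_order: Sequence[str] | None = None) -> tuple[list[str], np.ndarray]:
    """Unweighted mean of vertex signals within each region at every time point.

    ``vertex_to_region`` assigns a region label to every column of
    ``vertex_values``.  Returns the region labels (in ``region_order`` if
    given, else first-appearance order) and the time x region matrix.
    """
    vertex_values = np.asarray(vertex_values, dtype=float)
    if vertex_values.shape[1] != len(vertex_to_region):
        raise ValueError("one region label required per vertex column")
    labels = list(dict.fromkeys(vertex_to_region))
    if region_order is not None:
        unmapped = set(labels).difference(region_order)
        if unmapped:
            raise ValueError(f"vertices map to unknown regions: {sorted(unmapped)}")
        empty = [r for r in region_order if r not in labels]
        if empty:
            raise ValueError(f"regions with no vertices: {empty}")
        labels = list(region_order)
    cols = np.empty((vertex_values.shape[0], len(labels)))
    assignment = np.asarray(vertex_to_region)
    for j, lab in enumerate(labels):
        cols[:, j] = vertex_values[:, assignment == lab].mean(axis=1)
    return labels, cols


def detrend_linear(ts: TimeseriesRun) -> TimeseriesRun:
    """Remove the per-region least-squares line (slope and intercept)."""
    if ts.n_samples < 3:
        raise ValueError("detrending needs at least 3 samples")
    values = signal.detrend(ts.values, axis=0, type="linear")
    return replace(ts, values=values)


def bandpass(ts: TimeseriesRun, spec: BandpassSpec) -> TimeseriesRun:
    """Butterworth band-pass each region independently (zero-phase by default)."""
    spec.validate(ts.tr)
    sos = signal.butter(spec.order, [spec.low, spec.high], btype="bandpass",
                        fs=1.0 / ts.tr, output="sos")
    if spec.zero_phase:
        values = signal.sosfiltfilt(sos, ts.values, axis=0)
    else:
        values = signal.sosfilt(sos, ts.values, axis=0)
    return replace(ts, values=np.ascontiguousarray(values))


def average_cycles(ts: TimeseriesRun, design: RunDesign) -> TimeseriesRun:
    """Sample-wise mean of the three congruent cycle segments.

    Returns one cycle-length template per region (225 samples for the default
    design at TR 0.8 s); independent noise variance drops by the cycle count.
    """
    acq = AcquisitionParams(tr=ts.tr, n_samples=ts.n_samples)
    slices = cycle_sample_slices(design, acq)
    segments = np.stack([ts.values[s] for s in slices])
    meta = dict(ts.meta)
    meta["n_cycles_averaged"] = len(slices)
    return replace(ts, values=segments.mean(axis=0), meta=meta)
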