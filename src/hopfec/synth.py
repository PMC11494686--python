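"""Seeded synthetic cohorts: coupled Hopf oscillators plus paradigm-locked responses.

Each cortical region is a Stuart–Landau (Hopf normal form) oscillator with
state (x, y), bifurcation parameter ``a`` and intrinsic frequency ``omega``,
coupled diffusively through a nonnegative directed matrix C and driven by
additive Gaussian noise:

    dx_j = [(a_j - x_j^2 - y_j^2) x_j - omega_j y_j + G sum_i C[j,i] (x_i - x_j)] dt + sigma dW
    dy_j = [(a_j - x_j^2 - y_j^2) y_j + omega_j x_j + G sum_i C[j,i] (y_i - y_j)] dt + sigma dW

C is oriented from column to row: C[j, i] couples source region i into target
region j.  Below the bifurcation (a < 0) the noise sustains band-limited
fluctuations; above it (a > 0) the noiseless oscillator settles on a limit
cycle of radius sqrt(a).  Integration is Euler–Maruyama at step ``dt`` with a
discarded burn-in, and the x component subsampled at TR is the BOLD-like
signal.

Task structure is injected afterwards: a 5-s image boxcar convolved with a
canonical double-gamma haemodynamic response, added only to targeted
ROI / task / phase / hemisphere combinations with configurable gain and
per-subject jitter, so every downstream contrast has a known ground truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import gamma as gamma_dist

from .design import (AcquisitionParams, RunDesign, TASKS, build_task_design,
                     condition_mask, write_events_tsv)
from .parcellation import ParcellationScheme, ROISet, apriori_roi_sets
from .preprocess import TimeseriesRun


@dataclass(frozen=True)
class HopfParams:
    """Oscillator and integration parameters.

    a : bifurcation parameter (dimensionless; default -0.02, noise-driven regime)
    omega : intrinsic angular frequency, rad/s (default 2*pi*0.05, i.e. 0.05 Hz)
    G : global coupling scale (dimensionless)
    sigma : noise standard deviation, signal units
    dt : Euler–Maruyama step, s (TR must be an integer multiple)
    burn_in : discarded transient, s
    """

    a: float | np.ndarray = -0.02
    omega: float | np.ndarray = 2.0 * np.pi * 0.05
    G: float = 1.0
    sigma: float = 0.01
    dt: float = 0.1
    burn_in: float = 60.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.burn_in < 0:
            raise ValueError("burn_in must be nonnegative")


@dataclass(frozen=True)
class GroundTruthNetwork:
    """Nonnegative directed coupling matrix, oriented from column to row."""

    C: np.ndarray
    clip_max: float = 0.2

    def __post_init__(self):
        C = np.asarray(self.C, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("C must be square")
        if np.any(np.diag(C) != 0):
            raise ValueError("C must have a zero diagonal")
        if C.min() < 0 or C.max() > self.clip_max + 1e-12:
            raise ValueError(f"C entries must lie in [0, {self.clip_max}]")
        object.__setattr__(self, "C", C)

    @property
    def n_regions(self) -> int:
        return self.C.shape[0]


def make_ground_truth_network(n: int, density: float, strength_scale: float = 0.1,
                              seed: int = 0,
                              weight_range: tuple[float, float] | None = None
                              ) -> GroundTruthNetwork:
    """Random directed network: Bernoulli(density) edges, weights clipped to [0, 0.2].

    By default edge magnitudes are half-normal, |N(0, strength_scale)|.  For
    recovery benchmarks, where every true edge should be detectable,
    ``weight_range=(low, high)`` draws them uniformly bounded away from zero
    instead.  The diagonal is zero; the draw is seeded and deterministic.
    """
    if n < 2:
        raise ValueError("need at least 2 regions")
    if not 0 <= density <= 1:
        raise ValueError("density must lie in [0, 1]")
    if strength_scale < 0:
        raise ValueError("strength_scale must be nonnegative")
    rng = np.random.default_rng(seed)
    edges = rng.random((n, n)) < density
    if weight_range is not None:
        weights = rng.uniform(weight_range[0], weight_range[1], size=(n, n))
    else:
        weights = np.abs(rng.normal(0.0, strength_scale, size=(n, n)))
    C = np.where(edges, np.clip(weights, 0.0, 0.2), 0.0)
    np.fill_diagonal(C, 0.0)
    return GroundTruthNetwork(C)


def simulate_hopf(network: GroundTruthNetwork | np.ndarray, hopf: HopfParams,
                  acq: AcquisitionParams, seed: int | np.random.SeedSequence = 0,
                  return_y: bool = False) -> np.ndarray:
    """Integrate the coupled Hopf system; return the x component sampled at TR.

    The burn-in is simulated and discarded; the returned array has shape
    (acq.n_samples, n_regions).  With ``return_y`` a (x, y) tuple is returned.
    Raises on trajectory divergence, naming the offending step.
    """
    C = network.C if isinstance(network, GroundTruthNetwork) else np.asarray(network, float)
    n = C.shape[0]
    steps_per_sample = round(acq.tr / hopf.dt)
    if abs(steps_per_sample * hopf.dt - acq.tr) > 1e-9 or steps_per_sample < 1:
        raise ValueError(f"TR ({acq.tr}) must be an integer multiple of dt ({hopf.dt})")
    burn_steps = int(round(hopf.burn_in / hopf.dt))
    total_steps = burn_steps + acq.n_samples * steps_per_sample

    a = np.broadcast_to(np.asarray(hopf.a, float), (n,)).copy()
    omega = np.broadcast_to(np.asarray(hopf.omega, float), (n,)).copy()
    row_sum = C.sum(axis=1)
    noise_scale = hopf.sigma * np.sqrt(hopf.dt)

    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, 0.1, size=n)
    y = rng.normal(0.0, 0.1, size=n)

    out_x = np.empty((acq.n_samples, n))
    out_y = np.empty((acq.n_samples, n)) if return_y else None
    k = 0
    with np.errstate(over="ignore", invalid="ignore"):
        out_x, out_y = _integrate(C, a, omega, hopf, x, y, row_sum, noise_scale,
                                  total_steps, burn_steps, steps_per_sample, rng,
                                  out_x, out_y)
    if not np.isfinite(out_x).all():
        raise FloatingPointError("non-finite samples in Hopf output")
    return (out_x, out_y) if return_y else out_x


def _integrate(C, a, omega, hopf, x, y, row_sum, noise_scale, total_steps,
               burn_steps, steps_per_sample, rng, out_x, out_y):
    n = x.size
    return_y = out_y is not None
    k = 0
    for step in range(total_steps):
        if step >= burn_steps and (step - burn_steps) % steps_per_sample == 0:
            out_x[k] = x
            if return_y:
                out_y[k] = y
            k += 1
        r2 = x * x + y * y
        dx = (a - r2) * x - omega * y + hopf.G * (C @ x - row_sum * x)
        dy = (a - r2) * y + omega * x + hopf.G * (C @ y - row_sum * y)
        if noise_scale > 0:
            noise = rng.normal(0.0, noise_scale, size=2 * n)
            x = x + hopf.dt * dx + noise[:n]
            y = y + hopf.dt * dy + noise[n:]
        else:
            x = x + hopf.dt * dx
            y = y + hopf.dt * dy
        if step % 25 == 0 and not np.all(np.abs(x) < 1e6):
            raise FloatingPointError(f"Hopf trajectory diverged at step {step}")
    return out_x, out_y


# ---------------------------------------------------------------------------
# Paradigm-locked response injection
# ---------------------------------------------------------------------------

def double_gamma_hrf(t: np.ndarray, peak: float = 6.0, undershoot: float = 16.0,
                     ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response, peak normalized to 1."""
    t = np.asarray(t, dtype=float)
    h = gamma_dist.pdf(t, peak + 1.0) - ratio * gamma_dist.pdf(t, undershoot + 1.0)
    peak_val = h.max()
    return h / peak_val if peak_val > 0 else h


@dataclass(frozen=True)
class EffectSpec:
    """A paradigm-locked response added to one ROI/task/phase/hemisphere.

    ``gain`` multiplies ``base_amplitude`` (the peak response height, in signal
    units); ``phase`` is one of storage / recall / both, ``hemisphere`` one of
    L / R / both.  ``task=None`` applies to every task.
    """

    roi: str
    task: str | None = None
    phase: str = "both"
    hemisphere: str = "both"
    gain: float = 1.0
    base_amplitude: float = 0.02

    def __post_init__(self):
        if self.gain < 0:
            raise ValueError("gain must be nonnegative")
        if self.phase not in ("storage", "recall", "both"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.hemisphere not in ("L", "R", "both"):
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")


@dataclass
class SimulatedRun:
    """One synthetic acquisition: values plus its design and identity."""

    values: np.ndarray
    acq: AcquisitionParams
    design: RunDesign
    region_labels: list[str]
    participant: str
    task: str

    def as_timeseries(self) -> TimeseriesRun:
        return TimeseriesRun(self.values, self.acq.tr, list(self.region_labels),
                             meta={"participant": self.participant, "task": self.task})


_PHASE_IMAGE_EVENTS = {
    "storage": ("encoding_image",),
    "recall": ("retrieval_image",),
    "both": ("encoding_image", "retrieval_image"),
}


def paradigm_regressor(design: RunDesign, acq: AcquisitionParams, phase: str) -> np.ndarray:
    """Image boxcar of a phase convolved with the double-gamma HRF, at TR sampling."""
    boxcar = condition_mask(design, acq, _PHASE_IMAGE_EVENTS[phase]).astype(float)
    t = np.arange(0.0, 32.0, acq.tr)
    kernel = double_gamma_hrf(t)
    reg = np.convolve(boxcar, kernel)[: acq.n_samples]
    peak = np.abs(reg).max()
    return reg / peak if peak > 0 else reg


def apply_task_modulation(run: SimulatedRun, effects: Sequence[EffectSpec],
                          scheme: ParcellationScheme,
                          roi_sets: Mapping[str, ROISet],
                          subject_gain: float = 1.0) -> SimulatedRun:
    """Add paradigm-locked responses to the targeted regions only.

    Non-targeted regions are returned bit-identical.  ``subject_gain`` is the
    per-participant multiplicative jitter applied on top of every effect.
    """
    values = run.values.copy()
    for eff in effects:
        if eff.task is not None and eff.task != run.task:
            continue
        if eff.roi not in roi_sets:
            raise KeyError(f"effect references unknown ROI {eff.roi!r}")
        roi = roi_sets[eff.roi].scoped(eff.hemisphere)
        cols = roi.resolve(scheme)
        reg = paradigm_regressor(run.design, run.acq, eff.phase)
        values[:, cols] += (eff.base_amplitude * eff.gain * subject_gain * reg)[:, None]
    return replace(run, values=values)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Study conditions of one synthetic cohort.

    Defaults emulate the study design: 23 participants, three episodic-memory
    tasks, one 696-sample acquisition per task at TR = 0.8 s.  Per-subject
    heterogeneity is multiplicative log-normal jitter on effect gains and on
    coupling entries.
    """

    scheme: ParcellationScheme
    network: GroundTruthNetwork
    hopf: HopfParams = field(default_factory=HopfParams)
    effects: tuple[EffectSpec, ...] = ()
    n_participants: int = 23
    tasks: tuple[str, ...] = TASKS
    seed: int = 0
    subject_gain_jitter_sd: float = 0.2
    subject_coupling_jitter_sd: float = 0.1
    roi_sets: Mapping[str, ROISet] | None = None

    def __post_init__(self):
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if self.network.n_regions != self.scheme.n_regions:
            raise ValueError("network size does not match scheme size")
        for t in self.tasks:
            if t not in TASKS:
                raise ValueError(f"unknown task {t!r}")

    def resolved_roi_sets(self) -> Mapping[str, ROISet]:
        if self.roi_sets is not None:
            return self.roi_sets
        sets = {}
        for name, rs in _resolvable_apriori_sets(self.scheme).items():
            sets[name] = rs
        return sets


def _resolvable_apriori_sets(scheme: ParcellationScheme) -> dict[str, ROISet]:
    """Packaged ROI sets whose labels all resolve in the (possibly reduced) scheme."""
    try:
        return apriori_roi_sets(scheme)
    except KeyError:
        pass
    from .parcellation import _ROI_LABELS
    available = set(scheme.base_labels)
    return {name: ROISet(name, labels) for name, labels in _ROI_LABELS.items()
            if set(labels).issubset(available)}


def simulate_participant_run(spec: CohortSpec, participant_idx: int, task: str,
                             acq: AcquisitionParams | None = None) -> SimulatedRun:
    """One participant x task acquisition: jittered coupling, Hopf, modulation."""
    acq = acq or AcquisitionParams()
    task_idx = TASKS.index(task)
    ss = np.random.SeedSequence([spec.seed, participant_idx, task_idx])
    child_subject, child_sim = ss.spawn(2)
    rng = np.random.default_rng(child_subject)
    C = spec.network.C
    if spec.subject_coupling_jitter_sd > 0:
        jitter = rng.lognormal(0.0, spec.subject_coupling_jitter_sd, size=C.shape)
        C = np.clip(C * jitter, 0.0, spec.network.clip_max)
        np.fill_diagonal(C, 0.0)
    subject_gain = (rng.lognormal(0.0, spec.subject_gain_jitter_sd)
                    if spec.subject_gain_jitter_sd > 0 else 1.0)
    values = simulate_hopf(C, spec.hopf, acq, seed=child_sim)
    run = SimulatedRun(values, acq, build_task_design(task),
                       spec.scheme.column_labels, f"sub-{participant_idx + 1:02d}", task)
    return apply_task_modulation(run, spec.effects, spec.scheme,
                                 spec.resolved_roi_sets(), subject_gain)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def generate_cohort(spec: CohortSpec, out_dir: str | Path,
                    acq: AcquisitionParams | None = None) -> dict:
    """Write the full cohort to disk and return (and write) its manifest.

    Per participant x task: a timeseries TSV (n_samples x n_regions, header =
    region labels), a BIDS-style events TSV, and a JSON sidecar (TR, task,
    participant, seed).  The manifest lists every file with a SHA-256 digest
    and is written only after all files succeed (all-or-nothing).
    """
    acq = acq or AcquisitionParams()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for p in range(spec.n_participants):
        for task in spec.tasks:
            run = simulate_participant_run(spec, p, task, acq)
            stem = f"{run.participant}_task-{task}"
            ts_path = out / f"{stem}_bold.tsv"
            header = "\t".join(run.region_labels)
            np.savetxt(ts_path, run.values, fmt="%.6f", delimiter="\t",
                       header=header, comments="")
            ev_path = out / f"{stem}_events.tsv"
            write_events_tsv(run.design, ev_path)
            sidecar = {"TR": acq.tr, "n_samples": acq.n_samples, "task": task,
                       "participant": run.participant, "cohort_seed": spec.seed}
            sc_path = out / f"{stem}_bold.json"
            sc_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
            for path in (ts_path, ev_path, sc_path):
                files.append({"path": path.name, "sha256": _sha256(path)})
    manifest = {
        "seed": spec.seed,
        "n_participants": spec.n_participants,
        "tasks": list(spec.tasks),
        "n_regions": spec.scheme.n_regions,
        "region_labels": spec.scheme.column_labels,
        "acquisition": {"TR": acq.tr, "n_samples": acq.n_samples},
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def load_manifest(cohort_dir: str | Path) -> dict:
    path = Path(cohort_dir) / "manifest.json"
    if not path.exists():
        raise FileNotFoundError(f"no manifest.json in {cohort_dir}")
    return json.loads(path.read_text())


def load_run(cohort_dir: str | Path, participant: str, task: str) -> TimeseriesRun:
    """Read one participant x task timeseries TSV (+ sidecar) back as a run."""
    stem = Path(cohort_dir) / f"{participant}_task-{task}_bold"
    ts_path = stem.with_suffix(".tsv")
    if not ts_path.exists():
        raise FileNotFoundError(f"missing timeseries file {ts_path}")
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    with open(ts_path) as fh:
        labels = fh.readline().rstrip("\n").split("\t")
    values = np.loadtxt(ts_path, skiprows=1, delimiter="\t", ndmin=2)
    return TimeseriesRun(values, sidecar["TR"], labels,
                         meta={"participant": participant, "task": task})
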