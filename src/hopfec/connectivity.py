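"""Functional connectivity, lagged FC, and generative effective connectivity (GEC).

Functional connectivity (FC) is the Pearson correlation between band-passed
(0.008–0.08 Hz) region signals; it is symmetric and carries no direction.
Direction comes from the time-lagged FC: entry (i, j) of the lagged matrix is
corr(x_i(t), x_j(t + tau)), which is asymmetric when one region's activity
systematically leads another's.

GEC estimates a directed coupling matrix C for the whole-brain Hopf model by
iterative moment matching: starting from C = 0, each iteration simulates the
model with the current C, computes the simulated FC and lagged FC, and nudges
every off-diagonal entry by epsilon times the sum of the empirical-minus-
simulated FC and lagged-FC mismatches, clipping into [0, 0.2], until the
combined mean-squared mismatch stops improving.

Orientation convention: coupling matrices are read from column to row
(entry [r, c] is the influence of region c on region r).  For slow BOLD with
tau of about 2 s, the raw lag statistic loads the *reverse* of the generative
direction (the lead–lag signature at long delays reflects the return path),
so the fitted matrix is transposed before reporting by default
(``reverse_for_fmri``); on synthetic Hopf cohorts this reversal is what
recovers the generative coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .design import AcquisitionParams
from .preprocess import FC_BAND, BandpassSpec, TimeseriesRun, bandpass, detrend_linear
from .synth import HopfParams, simulate_hopf


@dataclass
class FCMatrix:
    """Symmetric Pearson correlation matrix over regions, with its band."""

    values: np.ndarray
    labels: list[str]
    band: BandpassSpec | None = None

    def __post_init__(self):
        V = np.asarray(self.values, dtype=float)
        if V.shape != (len(self.labels), len(self.labels)):
            raise ValueError("FC shape does not match labels")
        self.values = V


@dataclass
class LaggedFC:
    """Entry (i, j) = corr(x_i(t), x_j(t + lag)); asymmetric in general."""

    values: np.ndarray
    labels: list[str]
    lag_samples: int
    tau_seconds: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class GECConfig:
    """Hyperparameters of the GEC fit.

    tau_seconds : nominal lag of the delayed FC (default 2.0 s)
    epsilon : update step on each coupling entry per iteration
    max_iter / patience : iteration budget and early-stop window
    clip_min / clip_max : admissible coupling range (cap 0.2)
    sim_length_samples : samples simulated per iteration (None = match data)
    seed : base seed; iteration i simulates with SeedSequence([seed, i])
    reverse_for_fmri : transpose the fitted matrix before returning
    """

    tau_seconds: float = 2.0
    epsilon: float = 2e-3
    max_iter: int = 300
    patience: int = 100
    clip_min: float = 0.0
    clip_max: float = 0.2
    sim_length_samples: int | None = None
    seed: int = 0
    reverse_for_fmri: bool = True

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not self.clip_min < self.clip_max:
            raise ValueError("clip_min must be below clip_max")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    def lag_samples(self, tr: float) -> int:
        """Integer lag: tau/TR rounded half away from zero (2.0 s at TR 0.8 -> 3)."""
        ratio = self.tau_seconds / tr
        lag = int(np.floor(ratio + 0.5))
        if lag < 1:
            raise ValueError(f"tau {self.tau_seconds} s is below one TR ({tr} s)")
        return lag


@dataclass
class ECMatrix:
    """Directed coupling estimate, read from column to row, clipped to [0, 0.2]."""

    values: np.ndarray
    labels: list[str]
    reversed: bool = False
    orientation: str = "column->row"
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        V = np.asarray(self.values, dtype=float)
        if np.any(np.diag(V) != 0):
            raise ValueError("EC diagonal must be zero")
        self.values = V


# ---------------------------------------------------------------------------
# Empirical statistics
# ---------------------------------------------------------------------------

def _check_variance(values: np.ndarray, labels: Sequence[str]) -> None:
    sd = values.std(axis=0)
    # tolerance: constant columns leave rounding residue ~eps * magnitude
    dead = np.flatnonzero(sd <= 1e-12 * (1.0 + np.abs(values).max()))
    if dead.size:
        raise ValueError(f"zero-variance region(s): {[labels[i] for i in dead]}")


def functional_connectivity(ts: TimeseriesRun,
                            band: BandpassSpec | None = FC_BAND) -> FCMatrix:
    """Band-pass (unless band is None) then pairwise Pearson correlation."""
    if band is not None:
        ts = bandpass(detrend_linear(ts), band)
    if ts.n_samples < 3:
        raise ValueError("need at least 3 samples for correlation")
    _check_variance(ts.values, ts.region_labels)
    values = np.corrcoef(ts.values, rowvar=False)
    return FCMatrix(values=values, labels=list(ts.region_labels), band=band)


def lagged_correlation(values: np.ndarray, lag: int) -> np.ndarray:
    """Matrix of corr(x_i(t), x_j(t+lag)) for all region pairs (lag >= 0)."""
    T = values.shape[0]
    if not 0 <= lag < T - 2:
        raise ValueError(f"lag {lag} out of range for {T} samples")
    A = values[: T - lag]
    B = values[lag:]
    A = (A - A.mean(axis=0)) / A.std(axis=0)
    B = (B - B.mean(axis=0)) / B.std(axis=0)
    return (A.T @ B) / A.shape[0]


def lagged_fc(ts: TimeseriesRun, lag_samples: int,
              band: BandpassSpec | None = FC_BAND) -> LaggedFC:
    """Time-lagged FC of one run (band-passed like plain FC unless band is None)."""
    if band is not None:
        ts = bandpass(detrend_linear(ts), band)
    _check_variance(ts.values, ts.region_labels)
    values = lagged_correlation(ts.values, lag_samples)
    return LaggedFC(values=values, labels=list(ts.region_labels),
                    lag_samples=lag_samples, tau_seconds=lag_samples * ts.tr)


def fisher_z_mean(matrices: Sequence[np.ndarray]) -> np.ndarray:
    """Fisher-z average of correlation matrices (diagonal passed through)."""
    stack = np.stack([np.asarray(m, float) for m in matrices])
    z = np.arctanh(np.clip(stack, -0.999999, 0.999999))
    mean = np.tanh(z.mean(axis=0))
    # exact-1 diagonals saturate arctanh; restore them
    diag_mean = stack.mean(axis=0).diagonal()
    np.fill_diagonal(mean, diag_mean)
    return mean


# ---------------------------------------------------------------------------
# GEC fitting
# ---------------------------------------------------------------------------

def _offdiag(mat: np.ndarray) -> np.ndarray:
    n = mat.shape[0]
    return mat[~np.eye(n, dtype=bool)]


def fit_gec(fc_emp: FCMatrix, lagfc_emp: LaggedFC, hopf: HopfParams,
            config: GECConfig, tr: float = 0.8) -> ECMatrix:
    """Fit the Hopf-model coupling to empirical FC and lagged FC.

    Per iteration: simulate the model with the current coupling (seeded from
    (config.seed, iteration)), measure simulated FC and lagged FC at the same
    lag and through the same band-pass as the empirical matrices (``fc_emp.band``),
    update C_ij += epsilon * [(fc_emp - fc_sim) + (lagfc_emp -
    lagfc_sim)]_ij off the diagonal, and clip into [clip_min, clip_max].
    Iteration stops when the moving-average combined off-diagonal MSE has not
    improved for ``patience`` iterations; the final iterate is returned.  With
    ``reverse_for_fmri`` the returned matrix is the transpose of the raw fit.
    """
    if fc_emp.labels != lagfc_emp.labels:
        raise ValueError("FC and lagged FC label mismatch")
    n = len(fc_emp.labels)
    lag = lagfc_emp.lag_samples
    n_sim = config.sim_length_samples or 696
    acq = AcquisitionParams(tr=tr, n_samples=n_sim)
    band = fc_emp.band

    # The per-iteration error is a noisy estimate (one finite simulation), so
    # convergence is judged on a 10-iteration moving average and the *final*
    # iterate is returned: the argmin of the raw error sequence is an
    # extreme-value artifact that systematically picks under-converged C.
    C = np.zeros((n, n))
    errors: list[float] = []
    best_smoothed = np.inf
    since_best = 0
    window = 10
    for it in range(config.max_iter):
        seed = np.random.SeedSequence([config.seed, it])
        x = simulate_hopf(C, hopf, acq, seed=seed)
        if not np.isfinite(x).all():
            raise FloatingPointError(f"non-finite simulation at iteration {it}")
        if band is not None:
            # simulated moments go through the same band as the empirical ones
            sim_ts = TimeseriesRun(x, tr, fc_emp.labels)
            x = bandpass(detrend_linear(sim_ts), band).values
        sd = x.std(axis=0)
        if np.any(sd == 0):
            raise FloatingPointError(f"degenerate simulated region at iteration {it}")
        fc_sim = np.corrcoef(x, rowvar=False)
        lag_sim = lagged_correlation(x, lag)
        d_fc = fc_emp.values - fc_sim
        d_lag = lagfc_emp.values - lag_sim
        err = float(np.mean(_offdiag(d_fc) ** 2) + np.mean(_offdiag(d_lag) ** 2))
        errors.append(err)
        smoothed = float(np.mean(errors[-window:]))
        if it >= window - 1:
            if smoothed < best_smoothed:
                best_smoothed = smoothed
                since_best = 0
            else:
                since_best += 1
                if since_best >= config.patience:
                    break
        C = C + config.epsilon * (d_fc + d_lag)
        np.fill_diagonal(C, 0.0)
        C = np.clip(C, config.clip_min, config.clip_max)

    running_min = list(np.minimum.accumulate(errors))
    ec = ECMatrix(values=C, labels=list(fc_emp.labels), reversed=False,
                  diagnostics={"errors": errors, "running_min": running_min,
                               "best_error": float(running_min[-1]),
                               "n_iterations": len(errors), "lag_samples": lag})
    if config.reverse_for_fmri:
        ec = reverse_directionality(ec)
    return ec


def reverse_directionality(ec: ECMatrix) -> ECMatrix:
    """Transpose the coupling estimate and toggle the reversed flag.

    The column-to-row reading convention is preserved; the entry values swap
    across the diagonal.  Applying the operation twice restores the input.
    """
    return replace(ec, values=ec.values.T.copy(), reversed=not ec.reversed)


def directional_difference(ec: ECMatrix) -> np.ndarray:
    """Antisymmetric matrix D = C - C^T: positive where column->row dominates."""
    return ec.values - ec.values.T


def group_gec(fc_list: Sequence[FCMatrix], lagfc_list: Sequence[LaggedFC],
              hopf: HopfParams, config: GECConfig, tr: float = 0.8) -> ECMatrix:
    """Fisher-z-average participants' FC and lagged FC, then fit one group GEC."""
    if len(fc_list) < 1 or len(fc_list) != len(lagfc_list):
        raise ValueError("need matched, non-empty FC and lagged-FC collections")
    labels = fc_list[0].labels
    for m in list(fc_list) + list(lagfc_list):
        if m.labels != labels:
            raise ValueError("inconsistent labels across participants")
    lags = {l.lag_samples for l in lagfc_list}
    if len(lags) != 1:
        raise ValueError("inconsistent lag across participants")
    fc_mean = FCMatrix(fisher_z_mean([m.values for m in fc_list]), list(labels),
                       band=fc_list[0].band)
    lag_mean = LaggedFC(fisher_z_mean([m.values for m in lagfc_list]), list(labels),
                        lag_samples=lagfc_list[0].lag_samples,
                        tau_seconds=lagfc_list[0].tau_seconds)
    return fit_gec(fc_mean, lag_mean, hopf, config, tr=tr)


def split_indices(n: int, split_seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random split into halves of floor(n/2) and ceil(n/2) participants."""
    order = np.random.default_rng(split_seed).permutation(n)
    return order[: n // 2], order[n // 2:]


def split_half_reliability(fc_list: Sequence[FCMatrix], lagfc_list: Sequence[LaggedFC],
                           hopf: HopfParams, config: GECConfig,
                           split_seed: int = 0, tr: float = 0.8) -> float:
    """Correlation of group EC estimated from two random participant halves.

    Participants are split into halves of floor(n/2) and ceil(n/2) by a seeded
    shuffle; each half gets its own group GEC (both in the same orientation)
    and the off-diagonal entries are Pearson-correlated.
    """
    n = len(fc_list)
    if n < 4:
        raise ValueError("need at least 4 participants for a split-half estimate")
    half_a, half_b = split_indices(n, split_seed)
    ecs = []
    for half in (half_a, half_b):
        ecs.append(group_gec([fc_list[i] for i in half], [lagfc_list[i] for i in half],
                             hopf, config, tr=tr))
    a = _offdiag(ecs[0].values)
    b = _offdiag(ecs[1].values)
    return float(np.corrcoef(a, b)[0, 1])
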