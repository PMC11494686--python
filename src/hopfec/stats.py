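"""A-priori ROI contrasts: ROI means, paired t-tests, and the default battery.

Hypotheses are specified a priori per ROI (scene, semantic, Broca, reward,
intraparietal) and tested with paired t-tests across participants at a
two-tailed criterion of p < 0.02; no further multiplicity correction is
layered on top, the a-priori alpha being the stated policy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .activation import ActivationTable
from .parcellation import ParcellationScheme, ROISet


@dataclass(frozen=True)
class TestResult:
    t: float
    df: int
    p: float
    mean_a: float
    mean_b: float
    n: int
    significant: bool


@dataclass(frozen=True)
class ContrastSpec:
    """One a-priori contrast on ROI-mean activations.

    ``kind`` is ``task_vs_task`` (two task conditions in one phase) or
    ``storage_vs_recall`` (the two phases of one task).  A task side may be a
    tuple of task ids, in which case their ROI means are averaged per
    participant before testing.
    """

    name: str
    roi: str
    kind: str
    task_a: str | tuple[str, ...] = ""
    task_b: str | tuple[str, ...] = ""
    phase: str = "storage"
    task: str = ""                       # for storage_vs_recall
    alpha: float = 0.02
    hemisphere_scope: str = "both"

    def __post_init__(self):
        if self.kind not in ("task_vs_task", "storage_vs_recall"):
            raise ValueError(f"unknown contrast kind {self.kind!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def roi_mean(table: ActivationTable, roi: ROISet, scheme: ParcellationScheme) -> pd.Series:
    """Per-participant unweighted mean activation over the ROI's regions."""
    positions = roi.resolve(scheme)
    values = table.values.to_numpy(dtype=float)[:, positions]
    return pd.Series(values.mean(axis=1), index=table.values.index)


def paired_t(a: Sequence[float], b: Sequence[float], alpha: float = 0.02) -> TestResult:
    """Paired t-test: t = mean(d) / (sd(d)/sqrt(n)) with d = a - b, df = n - 1.

    Zero-variance differences are reported as t = +/-inf with p = 0 when the
    mean difference is nonzero, and t = 0 with p = 1 when all differences
    vanish.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("paired_t needs two equal-length vectors of n >= 2")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in paired_t input")
    d = a - b
    n = d.size
    df = n - 1
    sd = d.std(ddof=1)
    md = d.mean()
    if sd == 0:
        if md == 0:
            t, p = 0.0, 1.0
        else:
            t, p = float(np.sign(md)) * np.inf, 0.0
    else:
        t = md / (sd / np.sqrt(n))
        p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(t=float(t), df=df, p=float(p), mean_a=float(a.mean()),
                      mean_b=float(b.mean()), n=n, significant=bool(p < alpha))


def _tasks_tuple(side: str | tuple[str, ...]) -> tuple[str, ...]:
    return (side,) if isinstance(side, str) else tuple(side)


def _side_mean(tables: Mapping[tuple[str, str], ActivationTable],
               tasks: tuple[str, ...], phase: str, roi: ROISet,
               scheme: ParcellationScheme) -> pd.Series:
    means = []
    for task in tasks:
        key = (task, phase)
        if key not in tables:
            raise KeyError(f"missing activation table for task={task!r}, phase={phase!r}")
        means.append(roi_mean(tables[key], roi, scheme))
    return sum(means[1:], start=means[0]) / len(means)


def run_contrast_battery(tables: Mapping[tuple[str, str], ActivationTable],
                         specs: Sequence[ContrastSpec],
                         scheme: ParcellationScheme,
                         roi_sets: Mapping[str, ROISet]) -> pd.DataFrame:
    """Evaluate every contrast; one row per spec with t, df, p, and the flag.

    ``tables`` maps (task, phase) to the cohort's ActivationTable.
    """
    rows = []
    for spec in specs:
        if spec.roi not in roi_sets:
            raise KeyError(f"contrast {spec.name!r}: unknown ROI {spec.roi!r}")
        roi = roi_sets[spec.roi].scoped(spec.hemisphere_scope)
        if spec.kind == "task_vs_task":
            a = _side_mean(tables, _tasks_tuple(spec.task_a), spec.phase, roi, scheme)
            b = _side_mean(tables, _tasks_tuple(spec.task_b), spec.phase, roi, scheme)
            contrast = (f"{'+'.join(_tasks_tuple(spec.task_a))} vs "
                        f"{'+'.join(_tasks_tuple(spec.task_b))} ({spec.phase})")
        else:
            a = _side_mean(tables, (spec.task,), "storage", roi, scheme)
            b = _side_mean(tables, (spec.task,), "recall", roi, scheme)
            contrast = f"storage vs recall ({spec.task})"
        res = paired_t(a.to_numpy(), b.to_numpy(), alpha=spec.alpha)
        rows.append({"name": spec.name, "roi": spec.roi, "contrast": contrast,
                     "t": res.t, "df": res.df, "p": res.p,
                     "mean_a": res.mean_a, "mean_b": res.mean_b,
                     "significant": res.significant})
    columns = ["name", "roi", "contrast", "t", "df", "p", "mean_a", "mean_b",
               "significant"]
    return pd.DataFrame(rows, columns=columns)


def default_battery(alpha: float = 0.02) -> list[ContrastSpec]:
    """The packaged a-priori contrast battery.

    Scene-stream selectivity for the location tasks (storage and recall),
    semantic and Broca selectivity for the word-pair task, reward-system
    selectivity for reward-location storage, intraparietal selectivity for
    the location tasks, and storage-versus-recall effects for the semantic,
    Broca and reward systems.
    """
    OL, RL, WP = "object_location", "reward_location", "word_pair"
    mk = ContrastSpec
    return [
        mk("scene_storage", "scene", "task_vs_task", OL, WP, "storage", alpha=alpha),
        mk("scene_recall", "scene", "task_vs_task", OL, WP, "recall", alpha=alpha),
        mk("semantic_storage", "semantic", "task_vs_task", WP, (OL, RL), "storage",
           alpha=alpha),
        mk("broca_storage", "broca", "task_vs_task", WP, OL, "storage", alpha=alpha),
        mk("reward_storage", "reward", "task_vs_task", RL, OL, "storage", alpha=alpha),
        mk("intraparietal_storage", "intraparietal", "task_vs_task", (OL, RL), WP,
           "storage", alpha=alpha),
        mk("semantic_storage_vs_recall", "semantic", "storage_vs_recall", task=WP,
           alpha=alpha),
        mk("broca_storage_vs_recall", "broca", "storage_vs_recall", task=WP,
           alpha=alpha),
        mk("reward_storage_vs_recall", "reward", "storage_vs_recall", task=RL,
           alpha=alpha),
    ]
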