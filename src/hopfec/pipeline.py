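"""Stage runners binding the library into the reproducible shell pipeline.

Each command reads its inputs from the configured output directory, writes
tab-separated artifacts with JSON sidecars (config digest + seed), and is a
pure function of (inputs, configuration, seed): rerunning a stage with
unchanged inputs reproduces its artifacts byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .activation import ActivationTable, compute_activation, hemisphere_mean, laterality
from .config import PipelineConfig
from .connectivity import directional_difference, functional_connectivity, group_gec, lagged_fc
from .matio import write_ec, write_matrix
from .preprocess import TimeseriesRun
from .stats import default_battery, run_contrast_battery
from .synth import generate_cohort, load_manifest, load_run

log = logging.getLogger("hopfec")

PHASES_ANALYZED = ("storage", "recall")

COMMANDS = ("simulate", "activation", "gec", "stats", "report")


def _sidecar(path: Path, config: PipelineConfig, **extra) -> None:
    payload = {"config_digest": config.digest(), "seed": config.seed, **extra}
    path.with_suffix(".json").write_text(json.dumps(payload, indent=1, sort_keys=True))


def _cohort_dir(config: PipelineConfig) -> Path:
    return Path(config.out_dir) / "cohort"


def _activation_path(config: PipelineConfig, task: str, phase: str) -> Path:
    return Path(config.out_dir) / f"activation_task-{task}_phase-{phase}.tsv"


def run_simulate(config: PipelineConfig) -> list[Path]:
    spec = config.build_cohort_spec()
    out = _cohort_dir(config)
    log.info("simulating cohort: %d participants x %d tasks -> %s",
             spec.n_participants, len(spec.tasks), out)
    manifest = generate_cohort(spec, out, acq=config.acquisition)
    return [out / f["path"] for f in manifest["files"]] + [out / "manifest.json"]


def run_activation(config: PipelineConfig) -> list[Path]:
    cohort = _cohort_dir(config)
    if not (cohort / "manifest.json").exists():
        raise FileNotFoundError(f"missing cohort manifest: {cohort / 'manifest.json'} "
                                "(run 'simulate' first)")
    manifest = load_manifest(cohort)
    written = []
    for task in manifest["tasks"]:
        for phase in PHASES_ANALYZED:
            table = compute_activation(cohort, task, phase, config.activation_band)
            path = _activation_path(config, task, phase)
            table.values.to_csv(path, sep="\t", float_format="%.10g",
                                index_label="participant")
            _sidecar(path, config, task=task, phase=phase)
            written.append(path)
    return written


def _load_activation(config: PipelineConfig, task: str, phase: str) -> ActivationTable:
    path = _activation_path(config, task, phase)
    if not path.exists():
        raise FileNotFoundError(f"missing activation table: {path} (run 'activation' first)")
    values = pd.read_csv(path, sep="\t", index_col="participant")
    return ActivationTable(values=values, task=task, phase=phase)


def _hemisphere_run(ts: TimeseriesRun, scheme, hemisphere: str) -> TimeseriesRun:
    if hemisphere == "both":
        return ts
    pos = scheme.hemisphere_positions(hemisphere)
    return TimeseriesRun(ts.values[:, pos], ts.tr,
                         [ts.region_labels[i] for i in pos], meta=dict(ts.meta))


def run_gec(config: PipelineConfig, task: str | None = None,
            hemisphere: str | None = None) -> list[Path]:
    cohort = _cohort_dir(config)
    if not (cohort / "manifest.json").exists():
        raise FileNotFoundError(f"missing cohort manifest: {cohort / 'manifest.json'} "
                                "(run 'simulate' first)")
    manifest = load_manifest(cohort)
    scheme = config.build_scheme()
    hemisphere = hemisphere or config.gec_hemisphere
    tasks = [task] if task else manifest["tasks"]
    lag = config.gec.lag_samples(config.acquisition.tr)
    written = []
    for t in tasks:
        fcs, lagfcs = [], []
        for i in range(manifest["n_participants"]):
            ts = _hemisphere_run(load_run(cohort, f"sub-{i + 1:02d}", t), scheme, hemisphere)
            fcs.append(functional_connectivity(ts, config.fc_band))
            lagfcs.append(lagged_fc(ts, lag, config.fc_band))
        log.info("fitting group GEC: task=%s hemisphere=%s n=%d regions=%d",
                 t, hemisphere, len(fcs), len(fcs[0].labels))
        ec = group_gec(fcs, lagfcs, config.hopf, config.gec, tr=config.acquisition.tr)
        path = Path(config.out_dir) / f"gec_task-{t}_hemi-{hemisphere}.tsv"
        write_ec(ec, path, extra={"config_digest": config.digest(), "seed": config.seed,
                                  "task": t, "hemisphere": hemisphere,
                                  "band": [config.fc_band.low, config.fc_band.high]})
        written.append(path)
    return written


def run_stats(config: PipelineConfig) -> list[Path]:
    scheme = config.build_scheme()
    spec = config.build_cohort_spec()
    tables = {}
    for t in spec.tasks:
        for phase in PHASES_ANALYZED:
            tables[(t, phase)] = _load_activation(config, t, phase)
    battery = default_battery(alpha=config.battery_alpha)
    report = run_contrast_battery(tables, battery, scheme, spec.resolved_roi_sets())
    path = Path(config.out_dir) / "battery.tsv"
    report.to_csv(path, sep="\t", index=False, float_format="%.6g")
    _sidecar(path, config, alpha=config.battery_alpha)
    return [path]


def run_report(config: PipelineConfig) -> list[Path]:
    scheme = config.build_scheme()
    spec = config.build_cohort_spec()
    written = []
    act_rows, lat_rows = {}, {}
    grand_means = {}
    for t in spec.tasks:
        for phase in PHASES_ANALYZED:
            table = _load_activation(config, t, phase)
            hemi = hemisphere_mean(table, scheme)
            act_rows[f"{t}/{phase}"] = hemi.mean(axis=0)
            lat, grand = laterality(table, scheme)
            lat_rows[f"{t}/{phase}"] = lat.mean(axis=0)
            grand_means[f"{t}/{phase}"] = grand
    out = Path(config.out_dir)
    act = pd.DataFrame(act_rows).reindex(scheme.base_labels)
    act_path = out / "report_activation.tsv"
    act.to_csv(act_path, sep="\t", float_format="%.10g", index_label="region")
    _sidecar(act_path, config, statistic="mean RMSSD across participants, L/R mean")
    written.append(act_path)
    lat = pd.DataFrame(lat_rows).reindex(scheme.base_labels)
    lat_path = out / "report_laterality.tsv"
    lat.to_csv(lat_path, sep="\t", float_format="%.10g", index_label="region")
    _sidecar(lat_path, config, statistic="mean R-L RMSSD across participants",
             grand_mean_activation=grand_means)
    written.append(lat_path)
    for ec_path in sorted(out.glob("gec_task-*.tsv")):
        from .matio import read_ec
        ec = read_ec(ec_path)
        D = directional_difference(ec)
        d_path = out / ec_path.name.replace("gec_", "ec_asymmetry_")
        write_matrix(D, ec.labels, d_path,
                     sidecar={"config_digest": config.digest(), "seed": config.seed,
                              "statistic": "EC directional difference C - C^T",
                              "source": ec_path.name})
        written.append(d_path)
    return written


_RUNNERS = {"simulate": run_simulate, "activation": run_activation, "gec": run_gec,
            "stats": run_stats, "report": run_report}


def run_command(command: str, config: PipelineConfig, **kwargs) -> list[Path]:
    """Run one pipeline stage; returns the written artifact paths."""
    if command not in _RUNNERS:
        raise ValueError(f"unknown command {command!r}; expected one of {COMMANDS}")
    Path(config.out_dir).mkdir(parents=True, exist_ok=True)
    return _RUNNERS[command](config, **kwargs)
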