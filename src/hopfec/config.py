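"""Pipeline configuration: YAML/JSON loading with exhaustive validation.

A configuration file describes every stage of the pipeline: the parcellation,
the acquisition grid, the two analysis bands, the GEC hyperparameters, the
synthetic-cohort conditions, and the contrast battery.  Validation rejects
unknown keys (typo safety) and reports every problem found, not just the
first.  Omitted keys take the documented defaults; the packaged default
configuration validates cleanly and runs the whole pipeline at desk scale.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .connectivity import GECConfig
from .design import TASKS, AcquisitionParams
from .parcellation import ParcellationScheme, default_scheme, load_parcellation
from .preprocess import ACTIVATION_BAND, FC_BAND, BandpassSpec
from .synth import CohortSpec, EffectSpec, HopfParams, make_ground_truth_network


class ConfigError(ValueError):
    """Raised with the full list of configuration problems."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(problems))


_COHORT_KEYS = {"n_participants", "tasks", "base_labels", "density", "strength_scale",
                "network_seed", "subject_gain_jitter_sd", "subject_coupling_jitter_sd",
                "effects"}
_HOPF_KEYS = {"a", "f_hz", "G", "sigma", "dt", "burn_in"}
_GEC_KEYS = {"tau_seconds", "epsilon", "max_iter", "patience", "clip_min", "clip_max",
             "sim_length_samples", "reverse_for_fmri", "hemisphere"}
_BAND_KEYS = {"low", "high", "order", "zero_phase"}
_EFFECT_KEYS = {"roi", "task", "phase", "hemisphere", "gain", "base_amplitude"}
_TOP_KEYS = {"seed", "out_dir", "log_level", "scheme", "acquisition", "bands",
             "hopf", "gec", "cohort", "battery"}


@dataclass
class PipelineConfig:
    """Validated, fully-defaulted pipeline configuration."""

    seed: int = 0
    out_dir: str = "hopfec_out"
    log_level: str = "INFO"
    scheme_path: str | None = None
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    activation_band: BandpassSpec = ACTIVATION_BAND
    fc_band: BandpassSpec = FC_BAND
    hopf: HopfParams = field(default_factory=HopfParams)
    gec: GECConfig = field(default_factory=GECConfig)
    gec_hemisphere: str = "L"
    cohort: dict = field(default_factory=dict)
    battery_alpha: float = 0.02
    raw: dict = field(default_factory=dict)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True).encode()).hexdigest()[:16]

    def build_scheme(self) -> ParcellationScheme:
        scheme = (load_parcellation(self.scheme_path) if self.scheme_path
                  else default_scheme())
        base_labels = self.cohort.get("base_labels")
        return scheme.subset(base_labels) if base_labels else scheme

    def build_cohort_spec(self) -> CohortSpec:
        scheme = self.build_scheme()
        c = self.cohort
        network = make_ground_truth_network(
            scheme.n_regions, density=c.get("density", 0.15),
            strength_scale=c.get("strength_scale", 0.1),
            seed=c.get("network_seed", self.seed))
        effects = tuple(EffectSpec(**e) for e in c.get("effects", []))
        return CohortSpec(
            scheme=scheme, network=network, hopf=self.hopf, effects=effects,
            n_participants=c.get("n_participants", 23),
            tasks=tuple(c.get("tasks", TASKS)), seed=self.seed,
            subject_gain_jitter_sd=c.get("subject_gain_jitter_sd", 0.2),
            subject_coupling_jitter_sd=c.get("subject_coupling_jitter_sd", 0.1))


def _check_keys(section: dict, allowed: set, where: str, problems: list[str]) -> None:
    for key in section:
        if key not in allowed:
            problems.append(f"{where}: unknown key {key!r}")


def _band(raw: dict, default: BandpassSpec, where: str, problems: list[str]) -> BandpassSpec:
    _check_keys(raw, _BAND_KEYS, where, problems)
    spec = BandpassSpec(low=raw.get("low", default.low), high=raw.get("high", default.high),
                        order=raw.get("order", default.order),
                        zero_phase=raw.get("zero_phase", default.zero_phase))
    if not 0 <= spec.low < spec.high:
        problems.append(f"{where}: low ({spec.low}) must be below high ({spec.high})")
    return spec


def parse_config(raw: dict) -> PipelineConfig:
    """Validate a configuration mapping; raise ConfigError listing every problem."""
    problems: list[str] = []
    raw = raw or {}
    _check_keys(raw, _TOP_KEYS, "top level", problems)

    acq_raw = raw.get("acquisition", {}) or {}
    _check_keys(acq_raw, {"tr", "n_samples"}, "acquisition", problems)
    try:
        acq = AcquisitionParams(tr=acq_raw.get("tr", 0.8),
                                n_samples=int(acq_raw.get("n_samples", 696)))
    except ValueError as exc:
        problems.append(f"acquisition: {exc}")
        acq = AcquisitionParams()

    bands_raw = raw.get("bands", {}) or {}
    _check_keys(bands_raw, {"activation", "fc"}, "bands", problems)
    act_band = _band(bands_raw.get("activation", {}) or {}, ACTIVATION_BAND,
                     "bands.activation", problems)
    fc_band = _band(bands_raw.get("fc", {}) or {}, FC_BAND, "bands.fc", problems)
    for name, band in (("bands.activation", act_band), ("bands.fc", fc_band)):
        try:
            band.validate(acq.tr)
        except ValueError as exc:
            problems.append(f"{name}: {exc}")

    hopf_raw = raw.get("hopf", {}) or {}
    _check_keys(hopf_raw, _HOPF_KEYS, "hopf", problems)
    try:
        import numpy as np
        hopf = HopfParams(a=hopf_raw.get("a", -0.02),
                          omega=2.0 * np.pi * hopf_raw.get("f_hz", 0.05),
                          G=hopf_raw.get("G", 1.0), sigma=hopf_raw.get("sigma", 0.01),
                          dt=hopf_raw.get("dt", 0.1),
                          burn_in=hopf_raw.get("burn_in", 60.0))
    except ValueError as exc:
        problems.append(f"hopf: {exc}")
        hopf = HopfParams()

    gec_raw = dict(raw.get("gec", {}) or {})
    _check_keys(gec_raw, _GEC_KEYS, "gec", problems)
    gec_hemisphere = gec_raw.pop("hemisphere", "L")
    if gec_hemisphere not in ("L", "R", "both"):
        problems.append(f"gec.hemisphere: expected L, R or both, got {gec_hemisphere!r}")
    try:
        gec = GECConfig(seed=raw.get("seed", 0),
                        **{k: v for k, v in gec_raw.items() if k in _GEC_KEYS})
    except (TypeError, ValueError) as exc:
        problems.append(f"gec: {exc}")
        gec = GECConfig()

    cohort_raw = raw.get("cohort", {}) or {}
    _check_keys(cohort_raw, _COHORT_KEYS, "cohort", problems)
    for t in cohort_raw.get("tasks", []):
        if t not in TASKS:
            problems.append(f"cohort.tasks: unknown task {t!r}")
    density = cohort_raw.get("density", 0.15)
    if not 0 <= density <= 1:
        problems.append(f"cohort.density: must lie in [0, 1], got {density}")
    for i, eff in enumerate(cohort_raw.get("effects", []) or []):
        _check_keys(eff, _EFFECT_KEYS, f"cohort.effects[{i}]", problems)
        if "roi" not in eff:
            problems.append(f"cohort.effects[{i}]: missing required key 'roi'")

    battery_raw = raw.get("battery", {}) or {}
    _check_keys(battery_raw, {"alpha"}, "battery", problems)
    alpha = battery_raw.get("alpha", 0.02)
    if not 0 < alpha < 1:
        problems.append(f"battery.alpha: must lie in (0, 1), got {alpha}")

    if problems:
        raise ConfigError(problems)

    return PipelineConfig(
        seed=int(raw.get("seed", 0)), out_dir=str(raw.get("out_dir", "hopfec_out")),
        log_level=str(raw.get("log_level", "INFO")),
        scheme_path=raw.get("scheme"), acquisition=acq, activation_band=act_band,
        fc_band=fc_band, hopf=hopf, gec=gec, gec_hemisphere=gec_hemisphere,
        cohort=dict(cohort_raw), battery_alpha=alpha, raw=dict(raw))


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML or JSON configuration file."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is not None and not isinstance(raw, dict):
        raise ConfigError(["configuration root must be a mapping"])
    return parse_config(raw or {})


def default_config() -> PipelineConfig:
    """The packaged desk-scale default configuration."""
    with resources.as_file(resources.files("hopfec.data") / "default_config.yaml") as p:
        return load_config(str(p))
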