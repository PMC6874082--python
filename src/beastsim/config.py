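"""Run configuration: YAML serialisation and hashing.

A run is reproducible from (config, seed) alone; the config hash recorded
in CLI logs identifies the exact settings that produced an artifact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .behaviour import AgentParams, MixtureWeights
from .cohort import CohortConfig
from .errors import FormatError
from .task import DEFAULT_DELTAS


@dataclass(frozen=True)
class TaskSettings:
    n_rounds: int = 5
    deltas: tuple[float, ...] = DEFAULT_DELTAS
    true_count_min: int = 50
    true_count_max: int = 60


@dataclass(frozen=True)
class BankSettings:
    n_adults: int = 24
    n_students: int = 14
    n_iterations: int = 6


@dataclass(frozen=True)
class AnalysisSettings:
    filter_policy: str = "omit"
    alpha: float = 0.05
    include_school: bool = True
    random_effects: bool = True
    household_definition: str = "grandparents"
    glmm_rounds: str = "filtered"
    signed_deviations: bool = False


@dataclass(frozen=True)
class RunConfig:
    task: TaskSettings = field(default_factory=TaskSettings)
    bank: BankSettings = field(default_factory=BankSettings)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)
    seed: int = 0


def default_config() -> RunConfig:
    return RunConfig()


def _cohort_from_dict(d: dict) -> CohortConfig:
    kwargs = dict(d)
    for key in ("school_counts", "household_counts", "gender_counts", "aunts_uncles_rates"):
        if key in kwargs and isinstance(kwargs[key], dict):
            kwargs[key] = tuple(kwargs[key].items())
    if "agent_params" in kwargs and isinstance(kwargs["agent_params"], dict):
        ap = dict(kwargs["agent_params"])
        for wkey in ("peer_weights", "adult_weights"):
            if wkey in ap and not isinstance(ap[wkey], MixtureWeights):
                ap[wkey] = MixtureWeights(*ap[wkey])
        if "compromise_shape" in ap:
            ap["compromise_shape"] = tuple(ap["compromise_shape"])
        kwargs["agent_params"] = AgentParams(**ap)
    return CohortConfig(**kwargs)


def config_from_dict(d: dict) -> RunConfig:
    try:
        task = TaskSettings(**{**d.get("task", {}),
                               **({"deltas": tuple(d["task"]["deltas"])}
                                  if "deltas" in d.get("task", {}) else {})})
        bank = BankSettings(**d.get("bank", {}))
        cohort = _cohort_from_dict(d.get("cohort", {}))
        analysis = AnalysisSettings(**d.get("analysis", {}))
    except TypeError as exc:
        raise FormatError(f"malformed config: {exc}") from exc
    return RunConfig(task=task, bank=bank, cohort=cohort, analysis=analysis,
                     seed=int(d.get("seed", 0)))


def config_to_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    coh = d["cohort"]
    for key in ("school_counts", "household_counts", "gender_counts", "aunts_uncles_rates"):
        coh[key] = dict(coh[key])
    ap = coh["agent_params"]
    for wkey in ("peer_weights", "adult_weights"):
        w = ap[wkey]
        ap[wkey] = [w["p_stay"], w["p_copy"], w["p_contrarian"], w["p_overshoot"]]
    ap["compromise_shape"] = list(ap["compromise_shape"])
    d["task"]["deltas"] = list(d["task"]["deltas"])
    return d


def load_config(path) -> RunConfig:
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise FormatError(f"invalid YAML in {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise FormatError("config root must be a mapping")
    return config_from_dict(raw)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the canonical JSON form of a config."""
    canonical = json.dumps(config_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
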