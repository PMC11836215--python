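"""File formats and run bookkeeping: configs, trial-log CSV, policy JSON,
and run manifests.

All outputs are plain text and byte-stable for a fixed (config, seed), so
any artifact can be regenerated and diffed.  Unknown config fields are
rejected with a message naming the field; an empty config reproduces the
shipped incentive design exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .cohort import (
    DEFAULT_LEARNER_DISTS,
    CohortDesign,
    ParamDist,
)
from .metrics import SchemaError, validate_log
from .policy import BeliefState, PolicyTable
from .task import (
    GIVEUP,
    TRY,
    ConfigError,
    MatrixSpec,
    TaskConfig,
    TreatmentScheme,
)

TRIAL_LOG_COLUMNS = [
    "participant_id",
    "condition",
    "block",
    "round",
    "trial",
    "matrix",
    "key_id",
    "first_press",
    "raw_outcome",
    "scheme_delta",
    "cost_charged",
    "net_points",
    "label",
    "optimal",
]


def _reject_unknown(mapping: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = sorted(set(mapping) - allowed)
    if unknown:
        raise ConfigError(f"unknown field(s) {unknown} in {where}")


def _load_mapping(path: str | Path) -> dict:
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return data


def _matrix_spec(data: Mapping[str, Any], where: str, default: MatrixSpec) -> MatrixSpec:
    _reject_unknown(data, {"low_value", "high_value", "p_high", "n_keys"}, where)
    merged = {**asdict(default), **data}
    return MatrixSpec(**merged)


def load_task_config(
    path: str | Path,
) -> tuple[TaskConfig, dict[str, TreatmentScheme] | None]:
    """Load a task config; missing fields fall back to the shipped design.

    Returns ``(config, schemes)`` where ``schemes`` is a custom scheme
    table, or None to use the registry.
    """
    data = _load_mapping(path)
    return task_config_from_dict(data)


def task_config_from_dict(
    data: Mapping[str, Any],
) -> tuple[TaskConfig, dict[str, TreatmentScheme] | None]:
    allowed = {
        "try_spec",
        "giveup_spec",
        "trials_per_round",
        "rounds_per_block",
        "block_schemes",
        "analysis_window",
        "schemes",
    }
    _reject_unknown(data, allowed, "task config")
    default = TaskConfig()
    kwargs: dict[str, Any] = {}
    if "try_spec" in data:
        kwargs["try_spec"] = _matrix_spec(data["try_spec"], "try_spec", default.try_spec)
    if "giveup_spec" in data:
        kwargs["giveup_spec"] = _matrix_spec(
            data["giveup_spec"], "giveup_spec", default.giveup_spec
        )
    for field_name in ("trials_per_round", "rounds_per_block", "analysis_window"):
        if field_name in data:
            kwargs[field_name] = int(data[field_name])
    if "block_schemes" in data:
        kwargs["block_schemes"] = tuple(data["block_schemes"])
    config = TaskConfig(**{**{}, **kwargs})

    schemes: dict[str, TreatmentScheme] | None = None
    if "schemes" in data:
        schemes = {}
        for name, sdata in data["schemes"].items():
            _reject_unknown(
                sdata, {"outcome_delta", "exploration_cost"}, f"scheme {name!r}"
            )
            deltas = {}
            for key, v in sdata.get("outcome_delta", {}).items():
                matrix, _, level = key.partition("_")
                deltas[(matrix, level)] = float(v)
            costs = {
                m: float(c) for m, c in sdata.get("exploration_cost", {TRY: 2, GIVEUP: 2}).items()
            }
            schemes[name] = TreatmentScheme(name, deltas, costs)
    return config, schemes


def load_cohort_design(path: str | Path) -> CohortDesign:
    data = _load_mapping(path)
    return cohort_design_from_dict(data)


def cohort_design_from_dict(data: Mapping[str, Any]) -> CohortDesign:
    allowed = {
        "task",
        "conditions",
        "n_per_condition",
        "agent_mixture",
        "learner_dists",
        "initial_propensities",
        "threshold_m",
        "master_seed",
    }
    _reject_unknown(data, allowed, "cohort design")
    kwargs: dict[str, Any] = {}
    if "task" in data:
        config, _ = task_config_from_dict(data["task"])
        kwargs["task"] = config
    if "conditions" in data:
        kwargs["conditions"] = tuple(data["conditions"])
    if "n_per_condition" in data:
        kwargs["n_per_condition"] = tuple(int(n) for n in data["n_per_condition"])
    if "agent_mixture" in data:
        kwargs["agent_mixture"] = {k: float(v) for k, v in data["agent_mixture"].items()}
    if "learner_dists" in data:
        dists = dict(DEFAULT_LEARNER_DISTS)
        for name, d in data["learner_dists"].items():
            if name not in DEFAULT_LEARNER_DISTS:
                raise ConfigError(f"unknown field(s) ['{name}'] in learner_dists")
            _reject_unknown(d, {"mean", "sd", "lower", "upper"}, f"learner_dists.{name}")
            dists[name] = ParamDist(**{**asdict(DEFAULT_LEARNER_DISTS[name]), **d})
        kwargs["learner_dists"] = dists
    if "initial_propensities" in data:
        kwargs["initial_propensities"] = tuple(
            float(v) for v in data["initial_propensities"]
        )
    if "threshold_m" in data:
        kwargs["threshold_m"] = int(data["threshold_m"])
    if "master_seed" in data:
        kwargs["master_seed"] = int(data["master_seed"])
    return CohortDesign(**kwargs)


def write_trial_log(log: pd.DataFrame, path: str | Path) -> None:
    """Write the trial log with the fixed column order, header mandatory."""
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in log.columns]
    optional_missing = [c for c in missing if c in ("label", "optimal")]
    required_missing = [c for c in missing if c not in ("label", "optimal")]
    if required_missing:
        raise SchemaError(f"trial log is missing columns {required_missing}")
    out = log.copy()
    for c in optional_missing:
        out[c] = "" if c == "label" else 0
    out = out[TRIAL_LOG_COLUMNS]
    out["first_press"] = out["first_press"].astype(int)
    out["optimal"] = out["optimal"].astype(int)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False, lineterminator="\n")


def read_trial_log(path: str | Path) -> pd.DataFrame:
    log = pd.read_csv(path)
    validate_log(log)
    return log


def policy_to_json(policy: PolicyTable, path: str | Path | None = None) -> str:
    """Serialise a policy table keyed by the 5-tuple state; round-trippable."""
    payload = {
        "scheme": policy.scheme_name,
        "config": {
            "trials_per_round": policy.config.trials_per_round,
            "analysis_window": policy.config.analysis_window,
            "try_spec": asdict(policy.config.try_spec),
            "giveup_spec": asdict(policy.config.giveup_spec),
        },
        "states": {
            ",".join(map(str, state)): {"action": action, "value": value}
            for state, (action, value) in sorted(policy.items())
        },
    }
    text = json.dumps(payload, indent=1, sort_keys=True)
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(text)
    return text


def policy_from_json(source: str | Path) -> PolicyTable:
    if isinstance(source, Path):
        text = source.read_text()
    else:
        text = source if source.lstrip().startswith("{") else Path(source).read_text()
    payload = json.loads(text)
    cfg = payload["config"]
    config = TaskConfig(
        try_spec=MatrixSpec(**cfg["try_spec"]),
        giveup_spec=MatrixSpec(**cfg["giveup_spec"]),
        trials_per_round=cfg["trials_per_round"],
        analysis_window=cfg.get("analysis_window", cfg["trials_per_round"]),
    )
    table = {}
    for key, entry in payload["states"].items():
        t, bt, bg, ut, ug = key.split(",")
        state = BeliefState(int(t), bt, bg, int(ut), int(ug))
        table[state] = (entry["action"], float(entry["value"]))
    return PolicyTable(table, config, payload["scheme"])


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass(frozen=True)
class RunManifest:
    command: str
    config_hash: str
    master_seed: int | None
    package_version: str
    outputs: Mapping[str, str]
    timestamp: str


def config_hash(obj: Any) -> str:
    """Stable hash of any jsonable config-like object."""

    def default(o: Any) -> Any:
        if hasattr(o, "__dict__"):
            return vars(o)
        if isinstance(o, Mapping):
            return dict(o)
        return str(o)

    canonical = json.dumps(obj, sort_keys=True, default=default)
    return hashlib.sha256(canonical.encode()).hexdigest()


def write_manifest(
    command: str,
    config_obj: Any,
    seed: int | None,
    output_paths: list[str | Path],
    manifest_path: str | Path,
) -> RunManifest:
    """Record what produced a set of artifacts, with their content hashes."""
    manifest = RunManifest(
        command=command,
        config_hash=config_hash(config_obj),
        master_seed=seed,
        package_version=__version__,
        outputs={str(p): _hash_file(Path(p)) for p in output_paths},
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    path = Path(manifest_path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(asdict(manifest), indent=1, sort_keys=True))
    return manifest
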