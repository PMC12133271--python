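"""YAML configuration handling and run manifests.

Grid configs mirror :class:`missaux.study.StudyGrid` field names; list
values denote grid axes, scalars fixed parameters.  Imputation configs for
the generic front-end declare the analysis formula and the imputation-model
terms in compact string syntax ('x', 'z^3', 'z^3:edu').
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import yaml

from .engine import FCSConfig, ImputationModelSpec
from .study import StudyGrid

__all__ = [
    "load_grid_config",
    "load_impute_config",
    "config_digest",
    "RunManifest",
]

_AXIS_FIELDS = ("rho_yz", "outcome_mech", "aux_mech", "pi_z", "pi_y", "rho_xy", "include_w")
_FIXED_FIELDS = ("n", "n_sim", "m", "burnin", "seed")


def load_grid_config(path: str | Path) -> StudyGrid:
    """Read a StudyGrid from YAML, validating all fields at once."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    errors = []
    kwargs = {}
    known = set(_AXIS_FIELDS) | set(_FIXED_FIELDS)
    for key in raw:
        if key not in known:
            errors.append(f"unknown field {key!r}")
    for key in _AXIS_FIELDS:
        if key in raw:
            vals = raw[key]
            kwargs[key] = tuple(vals) if isinstance(vals, (list, tuple)) else (vals,)
    for key in _FIXED_FIELDS:
        if key in raw:
            kwargs[key] = raw[key]
    if not errors:
        try:
            grid = StudyGrid(**kwargs)
            for _ in grid.cells():  # force per-cell validation
                pass
        except Exception as err:
            errors.append(str(err))
    if errors:
        raise ValueError("invalid grid config: " + "; ".join(errors))
    return StudyGrid(**kwargs)


def load_impute_config(path: str | Path) -> tuple[dict, tuple[ImputationModelSpec, ...], FCSConfig]:
    """Read the generic front-end config.

    Returns (analysis dict with 'outcome' and 'exposure', model specs, FCS
    settings).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    errors = []
    analysis = raw.get("analysis") or {}
    if "outcome" not in analysis or "exposure" not in analysis:
        errors.append("analysis must declare 'outcome' and 'exposure'")
    specs = []
    for model in raw.get("models", []):
        try:
            specs.append(
                ImputationModelSpec(model["target"], tuple(model.get("terms", ())))
            )
        except Exception as err:
            errors.append(f"model {model.get('target', '?')!r}: {err}")
    try:
        fcs = FCSConfig(
            m=int(raw.get("m", 1000)),
            burnin=int(raw.get("burnin", 25)),
            seed=int(raw.get("seed", 0)),
        )
    except Exception as err:
        errors.append(str(err))
        fcs = None
    if errors:
        raise ValueError("invalid imputation config: " + "; ".join(errors))
    return analysis, tuple(specs), fcs


def config_digest(obj) -> str:
    """Stable digest of a config dataclass: changes iff any field changes."""
    payload = json.dumps(asdict(obj), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


class RunManifest:
    """Accumulates per-scenario status and output paths for a grid run."""

    def __init__(self, seed: int, digest: str):
        self.seed = seed
        self.digest = digest
        self.started = datetime.now(timezone.utc).isoformat()
        self.finished: str | None = None
        self.scenarios: dict[str, str] = {}
        self.outputs: dict[str, str] = {}

    def record(self, scenario_id: str, status: str) -> None:
        self.scenarios[scenario_id] = status

    def add_output(self, label: str, path: str | Path) -> None:
        self.outputs[label] = str(path)

    def finish(self) -> None:
        self.finished = datetime.now(timezone.utc).isoformat()

    def write(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "config_digest": self.digest,
            "started": self.started,
            "finished": self.finished,
            "scenarios": self.scenarios,
            "outputs": self.outputs,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
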