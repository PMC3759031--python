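"""Run configuration, validation, logging, and tabular writers.

A run configuration bundles everything a simulation needs: file paths,
dynamics parameters, recognition-criterion settings, and the input-bank size.
Configurations live in a single JSON or YAML file; unknown keys are rejected
so typos fail loudly before any simulation runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from .dynamics import ParameterSet, Trajectory
from .experiments import BatchReport, CompetitorCurves
from .lexicon import Lexicon, profiles_table
from .recognition import RecognitionCriterion

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "save_config",
    "setup_logging",
    "write_trajectory_csv",
    "write_batch_csv",
    "write_curves_csv",
    "write_profiles_csv",
]

log = logging.getLogger("tisk")


class ConfigError(ValueError):
    """Raised for malformed or unknown configuration content."""


@dataclass(frozen=True)
class RunConfig:
    inventory_path: str | None = None
    lexicon_path: str | None = None
    output_dir: str = "."
    params: ParameterSet = field(default_factory=ParameterSet)
    criterion: RecognitionCriterion = field(default_factory=RecognitionCriterion)
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "inventory_path": self.inventory_path,
            "lexicon_path": self.lexicon_path,
            "output_dir": self.output_dir,
            "params": self.params.to_dict(),
            "criterion": {
                "kind": self.criterion.kind,
                "absolute_threshold": self.criterion.absolute_threshold,
                "margin": self.criterion.margin,
                "dwell": self.criterion.dwell,
            },
            "log_level": self.log_level,
        }


def _check_keys(given: dict, allowed: set[str], context: str) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(f"unknown {context} keys: {sorted(unknown)}")


def config_from_dict(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    top = {f.name for f in fields(RunConfig)}
    _check_keys(data, top, "config")
    kwargs = dict(data)
    if "params" in kwargs:
        pkeys = {f.name for f in fields(ParameterSet)}
        _check_keys(kwargs["params"], pkeys, "params")
        try:
            kwargs["params"] = ParameterSet(**kwargs["params"])
        except (TypeError, ValueError) as e:
            raise ConfigError(f"invalid params: {e}") from e
    if "criterion" in kwargs:
        ckeys = {f.name for f in fields(RecognitionCriterion)}
        _check_keys(kwargs["criterion"], ckeys, "criterion")
        try:
            kwargs["criterion"] = RecognitionCriterion(**kwargs["criterion"])
        except (TypeError, ValueError) as e:
            raise ConfigError(f"invalid criterion: {e}") from e
    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON (.json) or YAML (.yaml/.yml) configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text)
    elif path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        raise ConfigError(f"unsupported config format {path.suffix!r}")
    return config_from_dict(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    data = cfg.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    elif path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        raise ConfigError(f"unsupported config format {path.suffix!r}")


def setup_logging(level: str = "INFO") -> None:
    """Route package logs to stderr at the requested level."""
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


# ---------------------------------------------------------------------- #
# tabular writers (long-format CSV, deterministic ordering)


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    """Long format: cycle, layer, unit, activation."""
    frames = []
    for layer, labels, hist in (
        ("word", traj.words, traj.word_history),
        ("nphone", ["".join(u) for u in traj.nphones], traj.nphone_history),
    ):
        df = pd.DataFrame(hist, columns=labels)
        df.insert(0, "cycle", range(len(df)))
        long = df.melt(id_vars="cycle", var_name="unit", value_name="activation")
        long.insert(1, "layer", layer)
        frames.append(long)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_batch_csv(report: BatchReport, path: str | Path) -> None:
    report.to_frame().to_csv(path, index=False)


def write_curves_csv(curves: CompetitorCurves, path: str | Path) -> None:
    curves.to_frame().to_csv(path)


def write_profiles_csv(lex: Lexicon, path: str | Path) -> None:
    profiles_table(lex).to_csv(path)
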