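"""Run configuration, report headers and shared text-I/O helpers."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import pandas as pd
import yaml

from . import __version__
from .doe import DesignError, FactorSpec

__all__ = ["ConfigError", "RunConfig", "load_config", "config_hash", "report_header",
           "format_table"]


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration (one structured YAML file).

    ``response_columns`` names the per-organism response columns expected in
    the response table; ``stationary_window`` is the (start, end) day window
    used for stationary-phase slope estimation; ``evaluation_time`` is the
    harvest day at which the model-fitted product value is reported.
    """

    factors: tuple[FactorSpec, ...] = ()
    n_center: int = 8
    response_columns: tuple[str, ...] = ()
    stationary_window: tuple[float, float] = (5.0, 11.0)
    p0: float = 0.0
    s0: float = 20.0
    evaluation_time: float = 11.0
    seed: int = 0
    randomize: bool = False
    noise_sd: float = 0.0
    output_dir: str = "."

    def __post_init__(self):
        object.__setattr__(self, "factors", tuple(self.factors))
        object.__setattr__(self, "response_columns", tuple(self.response_columns))
        object.__setattr__(self, "stationary_window", tuple(self.stationary_window))
        if self.evaluation_time <= 0:
            raise ConfigError(f"evaluation_time must be > 0, got {self.evaluation_time}")
        if len(self.stationary_window) != 2 or self.stationary_window[0] >= self.stationary_window[1]:
            raise ConfigError(f"stationary_window must be (start, end) with start < end")
        if self.p0 < 0 or self.s0 < 0 or self.noise_sd < 0:
            raise ConfigError("p0, s0 and noise_sd must be >= 0")

    def to_dict(self) -> dict:
        return {
            "factors": [
                {"name": f.name, "low": f.low, "center": f.center, "high": f.high}
                for f in self.factors
            ],
            "n_center": int(self.n_center),
            "response_columns": list(self.response_columns),
            "stationary_window": list(self.stationary_window),
            "p0": self.p0,
            "s0": self.s0,
            "evaluation_time": self.evaluation_time,
            "seed": int(self.seed),
            "randomize": bool(self.randomize),
            "noise_sd": self.noise_sd,
            "output_dir": str(self.output_dir),
        }


def load_config(path, **overrides) -> RunConfig:
    """Load a YAML run configuration; keyword overrides win over file keys."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    doc.update({k: v for k, v in overrides.items() if v is not None})
    raw_factors = doc.pop("factors", [])
    try:
        factors = tuple(
            FactorSpec(str(e["name"]), float(e["low"]), float(e["center"]), float(e["high"]))
            for e in raw_factors
        )
    except DesignError as exc:
        raise ConfigError(str(exc)) from exc
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"{path}: malformed factor entry ({exc})") from exc
    known = {k for k in RunConfig.__dataclass_fields__ if k != "factors"}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    try:
        return RunConfig(factors=factors, **doc)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the canonical JSON form of a config."""
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def report_header(config: RunConfig, title: str) -> str:
    """Plain-text report header recording version, seed and config hash."""
    lines = [
        title,
        "=" * len(title),
        f"fermopt version: {__version__}",
        f"config hash:     {config_hash(config)}",
        f"seed:            {config.seed}",
        "",
    ]
    return "\n".join(lines)


def format_table(frame: pd.DataFrame, decimals: int = 4) -> str:
    """Fixed-precision text rendering of a table (reports use 4 decimals;
    machine-readable CSV exports keep full precision)."""
    return frame.to_string(index=False, float_format=lambda v: f"{v:.{decimals}f}")
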