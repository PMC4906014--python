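"""Run configuration, serialization and reproducibility metadata."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .responses import DEFAULT_BETA_LEVELS, DEFAULT_C_LEVELS


@dataclass
class SweepConfig:
    c_levels: list[float] = field(default_factory=lambda: [float(x) for x in DEFAULT_C_LEVELS])
    beta_levels: list[float] = field(default_factory=lambda: [float(x) for x in DEFAULT_BETA_LEVELS])
    n_trials: int = 300
    T: int = 9
    max_saccades: int = 8


@dataclass
class RunConfig:
    """All knobs of a simulation run.

    ``c`` is the preference strength (log-preference for right feedback),
    ``beta_prior`` the prior expectation of the inverse precision of policy
    beliefs, ``T`` the number of outcome epochs per trial and
    ``max_saccades`` the saccade budget (defaults to T - 1).
    """

    c: float = 2.0
    beta_prior: float = 1.0
    T: int = 6
    max_saccades: int | None = None
    seed: int = 1
    action_mode: str = "argmin"
    tie_break: str = "random"
    g_horizon: int | None = 1
    sweep: SweepConfig = field(default_factory=SweepConfig)
    out_dir: str = "."

    def __post_init__(self) -> None:
        if isinstance(self.sweep, dict):
            self.sweep = SweepConfig(**self.sweep)
        if self.c < 0:
            raise ValueError("c must be non-negative")
        if self.beta_prior <= 0:
            raise ValueError("beta_prior must be positive")
        if self.T < 2:
            raise ValueError("T must be at least 2")
        if self.max_saccades is not None and not 0 <= self.max_saccades <= self.T - 1:
            raise ValueError("max_saccades must lie in [0, T-1]")
        if self.action_mode not in ("argmin", "sampled"):
            raise ValueError(f"unknown action_mode {self.action_mode!r}")
        if self.tie_break not in ("lowest", "random"):
            raise ValueError(f"unknown tie_break {self.tie_break!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        return cls(**doc)


def load_config(path: str | Path) -> RunConfig:
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ValueError(f"config file {path} does not hold a mapping")
    return RunConfig.from_dict(doc)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def config_hash(config: RunConfig) -> str:
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_metadata(config: RunConfig) -> dict:
    """Provenance block logged with every run: config hash, seed, versions."""
    import scipy

    from . import __version__

    try:
        rev = subprocess.run(
            ["git", "rev-parse", "HEAD"],
            capture_output=True,
            text=True,
            timeout=5,
            check=False,
        ).stdout.strip() or None
    except (OSError, subprocess.SubprocessError):
        rev = None
    return {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "versions": {
            "epiforage": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
        },
        "git_revision": rev,
    }
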