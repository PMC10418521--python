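"""Run configuration: YAML loading, validation, and hashing.

A run config nests the generator settings (``synth``), the bandpass
edges, the dFC window length, and the experiment settings.  Unknown keys
are rejected and validation errors name the offending field with a
dotted path (e.g. ``bandpass.high_hz``).
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .connectivity import BandpassSpec, DEFAULT_HIGH_HZ, DEFAULT_LOW_HZ, DEFAULT_WINDOW_TRS
from .synthetic import SynthConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config", "config_hash"]


class ConfigError(ValueError):
    """Raised with a dotted field path when a config file is invalid."""


@dataclass(frozen=True)
class RunConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    low_hz: float = DEFAULT_LOW_HZ
    high_hz: float = DEFAULT_HIGH_HZ
    window_trs: int = DEFAULT_WINDOW_TRS
    metric: str = "cosine"
    task: str = "both"  # classification | regression | both
    n_iterations: int = 20
    include_window_exploit: bool = True
    include_cross_cohort: bool = False
    output_dir: str = "fcleak_output"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.metric not in ("cosine", "euclidean"):
            raise ConfigError(f"metric: must be cosine or euclidean, got {self.metric!r}")
        if self.task not in ("classification", "regression", "both"):
            raise ConfigError(f"task: must be classification, regression or both")
        if self.n_iterations < 1:
            raise ConfigError("n_iterations: must be >= 1")
        if self.window_trs < 3:
            raise ConfigError("window_trs: must be >= 3")
        try:
            self.bandpass  # validates edges against Nyquist
        except ValueError as exc:
            raise ConfigError(f"bandpass.high_hz/low_hz: {exc}") from exc

    @property
    def bandpass(self) -> BandpassSpec:
        return BandpassSpec(
            low_hz=self.low_hz, high_hz=self.high_hz, tr_seconds=self.synth.tr_seconds
        )

    @property
    def tasks(self) -> list:
        return ["classification", "regression"] if self.task == "both" else [self.task]


def _build_synth(raw: dict) -> SynthConfig:
    allowed = {f.name for f in dataclasses.fields(SynthConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"synth.{sorted(unknown)[0]}: unknown key")
    try:
        return SynthConfig(**raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"synth: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and fully validate a YAML run config, filling defaults."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    raw = dict(raw)
    synth_raw = raw.pop("synth", {})
    if not isinstance(synth_raw, dict):
        raise ConfigError("synth: must be a mapping")
    allowed = {f.name for f in dataclasses.fields(RunConfig)} - {"synth"}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"{sorted(unknown)[0]}: unknown key")
    synth = _build_synth(synth_raw)
    try:
        return RunConfig(synth=synth, **raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def config_to_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    # drop the None default so round-trips stay canonical
    if d["synth"].get("structure_seed") is None:
        d["synth"].pop("structure_seed")
    return d


def dump_config(config: RunConfig, path=None) -> str:
    """Canonical YAML serialization; dump(load(x)) parses to an equal config."""
    text = yaml.safe_dump(config_to_dict(config), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_hash(config: RunConfig) -> str:
    """Short stable hash identifying the config that produced an output."""
    return hashlib.sha256(dump_config(config).encode()).hexdigest()[:12]
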