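"""Pipeline configuration: analysis windows, grids, seeds, paths.

Defaults are the analysis constants used throughout: a -3.0 to -1.0 s
pre-choice baseline, a -0.5 to 0 s choice period, early (0.5-1.0 s) and
late (1.5-2.0 s) response periods, -0.9 to -0.3 s and 0.3-0.9 s
pre/post-outcome windows, a 300 ms / 10 ms sliding PSTH, the 9-regressor
GLM span of -1.0 to 1.5 s around outcome, the +/-0.2 cluster threshold
with a 99th-percentile criterion, and a 101 x 21 (q, v) belief grid.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised when a configuration file violates the schema."""


@dataclass(frozen=True)
class Windows:
    baseline: tuple[float, float] = (-3.0, -1.0)
    choice: tuple[float, float] = (-0.5, 0.0)
    early: tuple[float, float] = (0.5, 1.0)
    late: tuple[float, float] = (1.5, 2.0)
    pre_outcome: tuple[float, float] = (-0.9, -0.3)
    post_outcome: tuple[float, float] = (0.3, 0.9)
    ev_choice_selection: tuple[float, float] = (-0.9, -0.3)

    def __post_init__(self) -> None:
        for name, (a, b) in asdict(self).items():
            if not a < b:
                raise ConfigError(f"window {name!r} is not well-ordered: "
                                  f"({a}, {b})")


@dataclass(frozen=True)
class PipelineConfig:
    # task
    n_games: int = 12
    rounds_per_game: int = 5
    p_good: float = 0.7
    p_reversal: float = 0.5
    slot_p_win: float = 0.5
    slot_n_trials: int = 80
    # learner grid
    n_q: int = 101
    n_v: int = 21
    hazard_mode: str = "game_boundary"
    # PSTH / GLM
    psth_window: float = 0.3
    psth_step: float = 0.01
    psth_span: tuple[float, float] = (-3.0, 2.0)
    glm_span: tuple[float, float] = (-1.0, 1.5)
    windows: Windows = field(default_factory=Windows)
    # cluster statistics
    cluster_threshold: float = 0.2
    n_shuffle: int = 10_000
    n_perm_per_unit: int = 1_000
    cluster_percentile: float = 99.0
    # alphas
    alpha_selection: float = 0.05 / 2
    alpha_cluster: float = 0.01
    alpha_correlation: float = 0.01 / 3
    # envelope
    envelope_smooth_sd: float = 0.05
    n_boot: int = 10_000
    h_thresholds: tuple[float, float] = (1.0, 1.5)
    # provenance
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        for name in ("p_good", "p_reversal", "slot_p_win"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability, got {v}")
        for name in ("alpha_selection", "alpha_cluster", "alpha_correlation"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        for name in ("psth_span", "glm_span"):
            a, b = getattr(self, name)
            if not a < b:
                raise ConfigError(f"{name} is not well-ordered: ({a}, {b})")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["windows"] = {k: list(v) for k, v in d["windows"].items()}
        for key in ("psth_span", "glm_span", "h_thresholds"):
            d[key] = list(d[key])
        return d

    def config_hash(self) -> str:
        """Stable hash stamped onto every result this config produces."""
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


_TUPLE_KEYS = {"psth_span", "glm_span", "h_thresholds"}


def load_config(path) -> PipelineConfig:
    """Load a YAML config; missing keys get defaults, unknown keys fail."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}; "
                          f"valid keys: {sorted(known)}")
    if "windows" in data:
        w = data["windows"]
        wknown = set(Windows.__dataclass_fields__)
        wunknown = set(w) - wknown
        if wunknown:
            raise ConfigError(f"unknown window keys: {sorted(wunknown)}")
        data["windows"] = Windows(**{k: tuple(v) for k, v in w.items()})
    for key in _TUPLE_KEYS & set(data):
        data[key] = tuple(data[key])
    try:
        return PipelineConfig(**data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
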