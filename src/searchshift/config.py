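"""Pipeline configuration: the generative study conditions in one record.

The defaults describe the emulated study: 50 participants, 60 strategy-
discriminating (exp2) gamble pairs, a within-subject alternative-wise (ALT)
vs dimension-wise (DIM) task manipulation with counterbalanced order, a
population that is overwhelmingly EV-driven, strongly task-conditioned
search direction (bias 0.9 under ALT, 0.1 under DIM), and a moderate
coupling of each trial's realized search direction to the valuation rule
applied on that trial.  See docs/methods.md for the rationale behind each
default.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .exceptions import ConfigError

__all__ = ["RTParams", "PhiSpec", "PipelineConfig"]

TASKS = ("ALT", "DIM")
AGENT_STRATEGIES = ("EV", "MAXIMAX", "GUESS")


@dataclass(frozen=True)
class RTParams:
    """Log-normal decision-time model parameters.

    ``ln rt = baseline + task_effect * 1[ALT] - ev_slope * |dEV| + N(0, sd)``.
    Units: log-seconds per unit predictor; ``ev_slope`` per yuan.
    """

    baseline_log_s: float = 1.5
    task_effect_log_s: float = 0.16
    ev_slope_per_yuan: float = 0.006
    noise_sd_log_s: float = 0.3

    def __post_init__(self) -> None:
        if not self.noise_sd_log_s > 0:
            raise ConfigError("noise_sd_log_s must be positive")


@dataclass(frozen=True)
class PhiSpec:
    """Population distribution of the softmax sensitivity phi.

    ``kind='fixed'`` gives every agent ``value``; ``kind='lognormal'`` draws
    ``exp(N(mu, sigma))`` per participant.
    """

    kind: str = "fixed"
    value: float = 0.5
    mu: float = math.log(0.5)
    sigma: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "lognormal"):
            raise ConfigError(f"phi kind must be 'fixed' or 'lognormal', got {self.kind!r}")
        if self.kind == "fixed" and self.value < 0:
            raise ConfigError("fixed phi must be non-negative")
        if self.kind == "lognormal" and not self.sigma >= 0:
            raise ConfigError("lognormal sigma must be non-negative")

    def draw(self, rng) -> float:
        if self.kind == "fixed":
            return self.value
        return float(rng.lognormal(self.mu, self.sigma))


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the simulate-and-analyze pipeline."""

    seed: int = 0
    n_participants: int = 50
    n_pairs: int = 60
    stimulus_mode: str = "exp2"
    agent_mixture: dict[str, float] = field(
        default_factory=lambda: {"EV": 0.9, "MAXIMAX": 0.05, "GUESS": 0.05}
    )
    phi: PhiSpec = field(default_factory=PhiSpec)
    #: Multiplier on phi applied per task (equal by default; set ALT > DIM to
    #: emulate a direct task effect on choice sensitivity).
    phi_task_scale: dict[str, float] = field(
        default_factory=lambda: {"ALT": 1.0, "DIM": 1.0}
    )
    #: Probability that a transition is alternative-wise, per task.
    bias_alt: float = 0.9
    bias_dim: float = 0.1
    #: Strength (0..1) of the per-trial coupling between realized search
    #: direction and the valuation rule applied on that trial; 0 disconnects
    #: choice from search entirely.
    search_coupling: float = 0.5
    rt_params: RTParams = field(default_factory=RTParams)
    #: Transitions per trial are 1 + Poisson(transitions_mean).
    transitions_mean: float = 8.0
    fixation_median_ms: float = 250.0
    fixation_sigma_log: float = 0.4
    fixation_min_ms: float = 60.0
    #: Probability of replacing a fixation's duration with a sub-50 ms one
    #: (exercises the duration filter; off by default).
    p_short_fixation: float = 0.0
    n_boot: int = 5000
    output_dir: str = "results_run"

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_pairs < 1:
            raise ConfigError("n_participants and n_pairs must be positive")
        if self.stimulus_mode not in ("exp1", "exp2"):
            raise ConfigError(f"stimulus_mode must be exp1|exp2, got {self.stimulus_mode!r}")
        if set(self.agent_mixture) - set(AGENT_STRATEGIES):
            raise ConfigError(f"agent_mixture keys must be among {AGENT_STRATEGIES}")
        if any(v < 0 for v in self.agent_mixture.values()):
            raise ConfigError("agent_mixture proportions must be non-negative")
        if abs(sum(self.agent_mixture.values()) - 1.0) > 1e-9:
            raise ConfigError("agent_mixture proportions must sum to 1")
        for name in ("bias_alt", "bias_dim", "search_coupling", "p_short_fixation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if set(self.phi_task_scale) != set(TASKS):
            raise ConfigError(f"phi_task_scale must have keys {TASKS}")
        if self.n_boot < 0:
            raise ConfigError("n_boot must be >= 0")
        if not self.fixation_min_ms > 0 or not self.fixation_median_ms > 0:
            raise ConfigError("fixation durations must be positive")

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "rt_params" in d and isinstance(d["rt_params"], dict):
            d["rt_params"] = RTParams(**d["rt_params"])
        if "phi" in d and isinstance(d["phi"], dict):
            d["phi"] = PhiSpec(**d["phi"])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)
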