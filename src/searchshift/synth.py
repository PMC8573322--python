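"""Synthetic participants: choices, fixation sequences, and decision times.

The generator emulates the statistical structure the downstream analyses
assume, so the whole pipeline runs and is testable without any recorded
data:

* **Agents** hold a strategy (EV, MAXIMAX, or GUESS), a softmax sensitivity
  ``phi`` (optionally task-scaled), per-task search biases, and log-normal
  decision-time parameters.
* **Search** is a Markov walk over the four AOIs.  At each step the walk
  moves within the current option across dimensions (alternative-wise) with
  the task's bias probability, otherwise within the current dimension across
  options (dimension-wise).
* **Choice** follows the softmax over the agent's strategy valuations.  In
  the full experiment simulation, a ``search_coupling`` parameter lets the
  trial's *realized* alternative-wise proportion shift which valuation rule
  is applied on that trial, creating the causal chain
  task -> search direction -> strategy -> choice that the mediation analysis
  is designed to detect.  With coupling 0, search and choice are independent
  given task.
* **Decision time** is log-normal with an additive task effect and a
  negative slope in the absolute EV difference.

Randomness: one global seed; per-participant child streams are spawned
deterministically from it, so tables are byte-identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .config import PipelineConfig, RTParams
from .gambles import GamblePair, ev_value, generate_pairs, maximax_value
from .search import AOIS, Fixation, FixationSequence, count_transitions
from .strategy import choice_probability

__all__ = [
    "AgentSpec",
    "simulate_choice",
    "simulate_fixations",
    "simulate_rt",
    "simulate_experiment",
]


@dataclass(frozen=True)
class AgentSpec:
    """Generative description of one synthetic participant."""

    participant_id: str
    strategy: str  # "EV" | "MAXIMAX" | "GUESS"
    phi: float = 0.5
    bias_alt: float = 0.9
    bias_dim: float = 0.1
    phi_task_scale: Mapping[str, float] = field(
        default_factory=lambda: {"ALT": 1.0, "DIM": 1.0}
    )
    rt_params: RTParams = field(default_factory=RTParams)

    def __post_init__(self) -> None:
        if self.strategy not in ("EV", "MAXIMAX", "GUESS"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.phi < 0:
            raise ValueError("phi must be non-negative")
        for b in (self.bias_alt, self.bias_dim):
            if not 0.0 <= b <= 1.0:
                raise ValueError("search biases must be in [0, 1]")

    def phi_for(self, task: str) -> float:
        return self.phi * self.phi_task_scale.get(task, 1.0)

    def bias_for(self, task: str) -> float:
        return self.bias_alt if task == "ALT" else self.bias_dim


def _p_choose_a(strategy: str, phi: float, pair: GamblePair) -> float:
    if strategy == "GUESS":
        return 0.5
    value = ev_value if strategy == "EV" else maximax_value
    return choice_probability(value(pair.option_a), value(pair.option_b), phi)


def simulate_choice(
    agent: AgentSpec,
    pair: GamblePair,
    rng: np.random.Generator,
    *,
    task: str | None = None,
    strategy_override: str | None = None,
) -> str:
    """One Bernoulli softmax choice ('A' or 'B') for an agent on a pair.

    GUESS agents choose A with probability 1/2.  ``task`` applies the agent's
    per-task phi scaling; ``strategy_override`` substitutes the valuation
    rule for this single trial (used by the search-coupled experiment
    simulation).
    """
    strategy = strategy_override or agent.strategy
    phi = agent.phi_for(task) if task is not None else agent.phi
    p_a = _p_choose_a(strategy, phi, pair)
    return "A" if rng.random() < p_a else "B"


_ALT_MOVE = {"A_PROB": "A_OUT", "A_OUT": "A_PROB", "B_PROB": "B_OUT", "B_OUT": "B_PROB"}
_DIM_MOVE = {"A_PROB": "B_PROB", "B_PROB": "A_PROB", "A_OUT": "B_OUT", "B_OUT": "A_OUT"}


def _draw_duration(
    rng: np.random.Generator,
    median_ms: float,
    sigma_log: float,
    min_ms: float,
    p_short: float,
) -> float:
    if p_short > 0.0 and rng.random() < p_short:
        return float(rng.uniform(10.0, 49.9))
    for _ in range(100):  # truncate below by resampling
        d = float(rng.lognormal(math.log(median_ms), sigma_log))
        if d >= min_ms:
            return d
    return min_ms


def simulate_fixations(
    task: str,
    bias_alt: float,
    bias_dim: float,
    n_transitions: int,
    rng: np.random.Generator,
    *,
    participant_id: str = "sim",
    pair_id: str = "sim",
    start: str | None = None,
    median_ms: float = 250.0,
    sigma_log: float = 0.4,
    min_ms: float = 60.0,
    p_short: float = 0.0,
) -> FixationSequence:
    """Markov walk over the four AOIs producing ``n_transitions + 1`` fixations.

    Each step is alternative-wise with probability ``bias_alt`` (task ALT) or
    ``bias_dim`` (task DIM), else dimension-wise; the walk never repeats an
    AOI, so every step is one transition.  Durations are log-normal
    (median ``median_ms``, log-sd ``sigma_log``) truncated below at
    ``min_ms``; ``p_short`` optionally injects sub-50 ms fixations to
    exercise the duration filter.
    """
    if n_transitions < 1:
        raise ValueError("n_transitions must be >= 1")
    bias = bias_alt if task == "ALT" else bias_dim
    aoi = start if start is not None else AOIS[int(rng.integers(len(AOIS)))]
    if aoi not in AOIS:
        raise ValueError(f"unknown start AOI {aoi!r}")
    labels = [aoi]
    for _ in range(n_transitions):
        aoi = _ALT_MOVE[aoi] if rng.random() < bias else _DIM_MOVE[aoi]
        labels.append(aoi)
    fixes = tuple(
        Fixation(lab, _draw_duration(rng, median_ms, sigma_log, min_ms, p_short))
        for lab in labels
    )
    return FixationSequence(participant_id, task, pair_id, fixes)


def simulate_rt(
    agent: AgentSpec, task: str, pair: GamblePair, rng: np.random.Generator
) -> float:
    """Log-normal decision time in seconds for one trial."""
    p = agent.rt_params
    dev = abs(ev_value(pair.option_a) - ev_value(pair.option_b))
    mu = (
        p.baseline_log_s
        + (p.task_effect_log_s if task == "ALT" else 0.0)
        - p.ev_slope_per_yuan * dev
    )
    return float(math.exp(mu + rng.normal(0.0, p.noise_sd_log_s)))


def _build_agents(config: PipelineConfig, rng: np.random.Generator) -> list[AgentSpec]:
    n = config.n_participants
    # Largest-remainder apportionment of the mixture into whole agents.
    quotas = {s: config.agent_mixture.get(s, 0.0) * n for s in ("EV", "MAXIMAX", "GUESS")}
    counts = {s: int(math.floor(q)) for s, q in quotas.items()}
    short = n - sum(counts.values())
    for s in sorted(quotas, key=lambda s: quotas[s] - counts[s], reverse=True)[:short]:
        counts[s] += 1
    strategies = [s for s in ("EV", "MAXIMAX", "GUESS") for _ in range(counts[s])]
    agents = []
    for i, strat in enumerate(strategies):
        agents.append(
            AgentSpec(
                participant_id=f"S{i:03d}",
                strategy=strat,
                phi=config.phi.draw(rng),
                bias_alt=config.bias_alt,
                bias_dim=config.bias_dim,
                phi_task_scale=dict(config.phi_task_scale),
                rt_params=config.rt_params,
            )
        )
    return agents


def _trial_strategy(
    agent: AgentSpec, pi_alt: float, coupling: float, rng: np.random.Generator
) -> str:
    """Valuation rule applied on one trial under search-strategy coupling.

    With probability ``1 - coupling`` the agent follows its dispositional
    strategy; with probability ``coupling`` the rule follows the trial's
    realized alternative-wise proportion ``pi_alt`` (EV with probability
    pi_alt, maximax otherwise).  GUESS agents are unaffected.
    """
    if agent.strategy == "GUESS" or coupling == 0.0:
        return agent.strategy
    if rng.random() < coupling:
        return "EV" if rng.random() < pi_alt else "MAXIMAX"
    return agent.strategy


def simulate_experiment(
    config: PipelineConfig, pairs: list[GamblePair] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, list[GamblePair]]:
    """Simulate the full within-subject experiment.

    Every participant completes both tasks on the same stimulus set, task
    order counterbalanced across participants.  Returns the trial table
    (participant_id, task, pair_id, choice, rt_s, task_order), the fixation
    table (participant_id, task, pair_id, fixation_index, aoi, duration_ms),
    and the stimulus list.  Fully deterministic given ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    pair_ss, agent_ss, participants_ss = ss.spawn(3)
    if pairs is None:
        pairs = generate_pairs(
            config.n_pairs, config.stimulus_mode, rng=np.random.default_rng(pair_ss)
        )
    agents = _build_agents(config, np.random.default_rng(agent_ss))
    child_streams = participants_ss.spawn(len(agents))

    trial_rows: list[dict] = []
    fix_rows: list[dict] = []
    for idx, (agent, child) in enumerate(zip(agents, child_streams)):
        rng = np.random.default_rng(child)
        order = ("ALT", "DIM") if idx % 2 == 0 else ("DIM", "ALT")
        order_label = f"{order[0]}_FIRST"
        for task in order:
            for pair in pairs:
                n_trans = int(rng.poisson(config.transitions_mean)) + 1
                seq = simulate_fixations(
                    task,
                    agent.bias_alt,
                    agent.bias_dim,
                    n_trans,
                    rng,
                    participant_id=agent.participant_id,
                    pair_id=pair.pair_id,
                    median_ms=config.fixation_median_ms,
                    sigma_log=config.fixation_sigma_log,
                    min_ms=config.fixation_min_ms,
                    p_short=config.p_short_fixation,
                )
                counts = count_transitions(seq)
                directed = counts.r_alt + counts.r_dim
                pi_alt = counts.r_alt / directed if directed else 0.5
                rule = _trial_strategy(agent, pi_alt, config.search_coupling, rng)
                choice = simulate_choice(
                    agent, pair, rng, task=task, strategy_override=rule
                )
                rt = simulate_rt(agent, task, pair, rng)
                trial_rows.append(
                    {
                        "participant_id": agent.participant_id,
                        "task": task,
                        "pair_id": pair.pair_id,
                        "choice": choice,
                        "rt_s": rt,
                        "task_order": order_label,
                    }
                )
                for j, fx in enumerate(seq.fixations):
                    fix_rows.append(
                        {
                            "participant_id": agent.participant_id,
                            "task": task,
                            "pair_id": pair.pair_id,
                            "fixation_index": j,
                            "aoi": fx.aoi,
                            "duration_ms": fx.duration_ms,
                        }
                    )
    return pd.DataFrame(trial_rows), pd.DataFrame(fix_rows), pairs
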