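"""Risky gambles, gamble pairs, and stimulus generation.

A gamble here is the simplest risky prospect: a single nonzero gain
``outcome`` (integer yuan, 1-99) obtained with ``probability`` (an integer
percent, stored as a fraction in [0.01, 0.98]); otherwise nothing.  A
stimulus is a pair of such gambles with no dominance: one option offers the
larger amount, the other the larger probability.

Two stimulus regimes are supported:

* ``exp1`` -- random non-dominated pairs with a minimum expected-value gap;
* ``exp2`` -- pairs on which expected-value maximization and the maximax
  heuristic predict opposite choices (the higher-outcome option has the
  strictly lower expected value), which makes the two strategies maximally
  discriminable from choices alone.

Probabilities are stored and computed as fractions throughout; the integer
percent form exists only in serialized tables (see :mod:`searchshift.tables`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import StimulusError

__all__ = [
    "Gamble",
    "GamblePair",
    "ev_value",
    "maximax_value",
    "is_dominated",
    "generate_pairs",
    "EV_GAP_YUAN",
]

#: Minimum |EV(A) - EV(B)| for a generated pair, in yuan.  Every trial is
#: later coded as EV-consistent or not, which requires strictly unequal
#: expected values; the floor keeps that coding numerically unambiguous.
EV_GAP_YUAN = 0.5

_ATTEMPT_BUDGET = 10_000


@dataclass(frozen=True)
class Gamble:
    """A single-outcome risky prospect.

    Parameters
    ----------
    outcome : int
        Gain in yuan, integral, in [1, 99].
    probability : float
        Probability of the gain as a fraction; ``probability * 100`` must be
        integral and in [1, 98].
    """

    outcome: int
    probability: float

    def __post_init__(self) -> None:
        if not float(self.outcome).is_integer() or not (1 <= self.outcome <= 99):
            raise ValueError(f"outcome must be an integer in [1, 99], got {self.outcome!r}")
        pct = self.probability * 100.0
        if abs(pct - round(pct)) > 1e-9 or not (1 <= round(pct) <= 98):
            raise ValueError(
                f"probability must be an integer percent in [1, 98], got {self.probability!r}"
            )

    @property
    def percent(self) -> int:
        """Probability as the integer percent used on screen and on disk."""
        return int(round(self.probability * 100.0))


def ev_value(g: Gamble) -> float:
    """Expected value of a gamble in yuan: ``outcome * probability``."""
    return g.outcome * g.probability


def maximax_value(g: Gamble) -> float:
    """Maximax valuation: the best (here, only) outcome, ignoring probability."""
    return float(g.outcome)


def is_dominated(option_a: Gamble, option_b: Gamble) -> bool:
    """True iff one option weakly beats the other on both attributes, strictly on one.

    Identical options are not a dominance relation (no strict inequality);
    callers treat that case as degenerate separately.
    """
    a_ge = option_a.outcome >= option_b.outcome and option_a.probability >= option_b.probability
    b_ge = option_b.outcome >= option_a.outcome and option_b.probability >= option_a.probability
    if a_ge and b_ge:  # identical
        return False
    return a_ge or b_ge


@dataclass(frozen=True)
class GamblePair:
    """Two non-dominated gambles plus display metadata.

    ``option_a`` is the option displayed on top (responded to with the left
    key); ``risky_on_top`` records whether the riskier option -- the one with
    the greater outcome and lower probability -- is ``option_a``.
    """

    pair_id: str
    option_a: Gamble
    option_b: Gamble
    risky_on_top: bool = field(default=True)

    def __post_init__(self) -> None:
        if is_dominated(self.option_a, self.option_b):
            raise ValueError(f"pair {self.pair_id}: one option dominates the other")
        if self.option_a == self.option_b:
            raise ValueError(f"pair {self.pair_id}: options are identical")
        riskier_is_a = self.option_a.outcome > self.option_b.outcome
        if riskier_is_a != self.risky_on_top:
            raise ValueError(
                f"pair {self.pair_id}: risky_on_top={self.risky_on_top} does not match options"
            )

    @property
    def ev_a(self) -> float:
        return ev_value(self.option_a)

    @property
    def ev_b(self) -> float:
        return ev_value(self.option_b)

    def ev_favored(self) -> str:
        """Label ('A' or 'B') of the option with the strictly larger EV."""
        if self.ev_a == self.ev_b:
            raise ValueError(f"pair {self.pair_id}: equal expected values")
        return "A" if self.ev_a > self.ev_b else "B"

    def maximax_favored(self) -> str:
        """Label of the option with the larger outcome."""
        return "A" if self.option_a.outcome > self.option_b.outcome else "B"


def _accept(g1: Gamble, g2: Gamble, mode: str, min_ev_gap: float) -> bool:
    if is_dominated(g1, g2) or g1 == g2:
        return False
    if abs(ev_value(g1) - ev_value(g2)) < min_ev_gap:
        return False
    if mode == "exp2":
        hi, lo = (g1, g2) if g1.outcome > g2.outcome else (g2, g1)
        if ev_value(hi) >= ev_value(lo):
            return False
    return True


def generate_pairs(
    n: int,
    mode: str = "exp1",
    seed: int = 0,
    *,
    min_ev_gap: float = EV_GAP_YUAN,
    unique: bool = False,
    rng: np.random.Generator | None = None,
) -> list[GamblePair]:
    """Generate ``n`` stimulus pairs by rejection sampling.

    Outcomes are uniform integers on [1, 99] and probabilities uniform integer
    percents on [1, 98]; a candidate pair is kept iff it is non-dominated and
    its expected values differ by at least ``min_ev_gap`` yuan, and in mode
    ``exp2`` additionally the higher-outcome option has the strictly smaller
    expected value (so maximax and EV disagree on every pair).  The position
    of the riskier option alternates, giving a ceil(n/2)/floor(n/2)
    counterbalance.

    Raises
    ------
    StimulusError
        If a single pair exhausts the 10,000-attempt budget (infeasible
        constraints, e.g. an excessive ``min_ev_gap``).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mode not in ("exp1", "exp2"):
        raise ValueError(f"mode must be 'exp1' or 'exp2', got {mode!r}")
    if rng is None:
        rng = np.random.default_rng(seed)

    pairs: list[GamblePair] = []
    seen: set[tuple[int, int, int, int]] = set()
    for i in range(n):
        for _ in range(_ATTEMPT_BUDGET):
            x1, x2 = rng.integers(1, 100, size=2)
            p1, p2 = rng.integers(1, 99, size=2)
            g1 = Gamble(int(x1), p1 / 100.0)
            g2 = Gamble(int(x2), p2 / 100.0)
            if not _accept(g1, g2, mode, min_ev_gap):
                continue
            risky, safe = (g1, g2) if g1.outcome > g2.outcome else (g2, g1)
            key = (risky.outcome, risky.percent, safe.outcome, safe.percent)
            if unique and key in seen:
                continue
            seen.add(key)
            risky_on_top = i % 2 == 0
            a, b = (risky, safe) if risky_on_top else (safe, risky)
            pairs.append(GamblePair(f"P{i:03d}", a, b, risky_on_top=risky_on_top))
            break
        else:
            raise StimulusError(
                f"pair {i}: no admissible pair within {_ATTEMPT_BUDGET} attempts "
                f"(mode={mode}, min_ev_gap={min_ev_gap})"
            )
    return pairs
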