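"""Fixation filtering, AOI transition counting, and the search-measure index.

The stimulus board is a 2 x 2 grid of information cells (two options, two
dimensions), each an area of interest (AOI):

    A_PROB  A_OUT
    B_PROB  B_OUT

A *transition* is a step between fixations on distinct AOIs.  It is
*alternative-wise* when it stays within one option and crosses dimensions
(e.g. A_PROB -> A_OUT), *dimension-wise* when it stays within one dimension
and crosses options (A_PROB -> B_PROB), and *diagonal* otherwise.  Diagonals
count toward the total N but toward neither r_a nor r_d.

The Böckenholt-Hynan search measure aggregates the counts into

    SM = sqrt(N) * [ (D*A/N) * (r_a - r_d) - (D - A) ]
         / sqrt( A^2 * (D - 1) + D^2 * (A - 1) )

with A options and D dimensions; for the 2 x 2 board it reduces to
``sqrt(2) * (r_a - r_d) / sqrt(N)``.  Positive values mean predominantly
alternative-wise search, negative predominantly dimension-wise, and under
random transition targets the statistic is approximately standard normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import math

import numpy as np
import pandas as pd

__all__ = [
    "AOIS",
    "Fixation",
    "FixationSequence",
    "TransitionCounts",
    "filter_fixations",
    "count_transitions",
    "sm_index",
    "sm_per_trial",
    "sm_participant_means",
    "MIN_FIXATION_MS",
]

AOIS = ("A_PROB", "A_OUT", "B_PROB", "B_OUT")

#: Default minimum fixation duration retained, in ms (strictly shorter
#: fixations are artifacts of saccade segmentation and are dropped).
MIN_FIXATION_MS = 50.0


@dataclass(frozen=True)
class Fixation:
    aoi: str
    duration_ms: float

    def __post_init__(self) -> None:
        if self.aoi not in AOIS:
            raise ValueError(f"unknown AOI {self.aoi!r}")
        if not self.duration_ms > 0:
            raise ValueError("duration_ms must be positive")

    @property
    def option(self) -> str:
        return self.aoi[0]

    @property
    def dimension(self) -> str:
        return self.aoi[2:]


@dataclass(frozen=True)
class FixationSequence:
    """Ordered AOI fixations for one trial."""

    participant_id: str
    task: str
    pair_id: str
    fixations: tuple[Fixation, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixations", tuple(self.fixations))

    def aois(self) -> list[str]:
        return [f.aoi for f in self.fixations]


@dataclass(frozen=True)
class TransitionCounts:
    """Tally of transitions between distinct AOIs for one trial."""

    n_total: int
    r_alt: int
    r_dim: int
    r_diag: int

    def __post_init__(self) -> None:
        if min(self.n_total, self.r_alt, self.r_dim, self.r_diag) < 0:
            raise ValueError("counts must be non-negative")
        if self.r_alt + self.r_dim + self.r_diag != self.n_total:
            raise ValueError("r_alt + r_dim + r_diag must equal n_total")


def filter_fixations(
    seq: FixationSequence, min_ms: float = MIN_FIXATION_MS
) -> FixationSequence:
    """Drop fixations strictly shorter than ``min_ms``; order preserved."""
    kept = tuple(f for f in seq.fixations if f.duration_ms >= min_ms)
    return FixationSequence(seq.participant_id, seq.task, seq.pair_id, kept)


def _classify_step(a: str, b: str) -> str:
    same_option = a[0] == b[0]
    same_dim = a[2:] == b[2:]
    if same_option and not same_dim:
        return "alt"
    if same_dim and not same_option:
        return "dim"
    return "diag"


def count_transitions(seq: FixationSequence | Sequence[str]) -> TransitionCounts:
    """Count alternative-wise / dimension-wise / diagonal transitions.

    Consecutive fixations on the same AOI are merged first (a re-fixation is
    not a transition); every remaining step between distinct AOIs is one
    transition.  Accepts either a :class:`FixationSequence` or a bare list of
    AOI labels.
    """
    labels = seq.aois() if isinstance(seq, FixationSequence) else list(seq)
    for lab in labels:
        if lab not in AOIS:
            raise ValueError(f"unknown AOI {lab!r}")
    merged: list[str] = []
    for lab in labels:
        if not merged or merged[-1] != lab:
            merged.append(lab)
    r = {"alt": 0, "dim": 0, "diag": 0}
    for a, b in zip(merged, merged[1:]):
        r[_classify_step(a, b)] += 1
    total = r["alt"] + r["dim"] + r["diag"]
    return TransitionCounts(total, r["alt"], r["dim"], r["diag"])


def sm_index(
    counts: TransitionCounts, n_alternatives: int = 2, n_dimensions: int = 2
) -> float:
    """Böckenholt-Hynan search-measure index of one trial's transitions.

    Raises
    ------
    ValueError
        If ``counts.n_total`` is zero (no transitions, SM undefined).
    """
    if counts.n_total < 1:
        raise ValueError("SM index undefined for zero transitions")
    a, d, n = float(n_alternatives), float(n_dimensions), float(counts.n_total)
    num = (d * a / n) * (counts.r_alt - counts.r_dim) - (d - a)
    den = math.sqrt(a * a * (d - 1.0) + d * d * (a - 1.0))
    return math.sqrt(n) * num / den


def sm_per_trial(
    fixation_table: pd.DataFrame, min_ms: float = MIN_FIXATION_MS
) -> pd.DataFrame:
    """Per-trial transition counts and SM index from a long fixation table.

    Expects columns ``participant_id``, ``task``, ``pair_id``,
    ``fixation_index``, ``aoi``, ``duration_ms``.  Fixations shorter than
    ``min_ms`` are removed first.  Trials whose filtered, merged sequence has
    no transition between distinct AOIs get ``sm = NaN`` (they are excluded
    from aggregation).

    Returns the SM-table schema: one row per trial with counts and ``sm``.
    """
    required = {"participant_id", "task", "pair_id", "fixation_index", "aoi", "duration_ms"}
    missing = required - set(fixation_table.columns)
    if missing:
        raise KeyError(f"fixation table missing columns: {sorted(missing)}")
    df = fixation_table.sort_values(
        ["participant_id", "task", "pair_id", "fixation_index"], kind="stable"
    )
    df = df[df["duration_ms"] >= min_ms]
    rows = []
    keys = fixation_table[["participant_id", "task", "pair_id"]].drop_duplicates()
    grouped = dict(tuple(df.groupby(["participant_id", "task", "pair_id"], sort=False)))
    for key in keys.itertuples(index=False):
        k = (key.participant_id, key.task, key.pair_id)
        block = grouped.get(k)
        labels = [] if block is None else list(block["aoi"])
        counts = count_transitions(labels)
        sm = sm_index(counts) if counts.n_total >= 1 else float("nan")
        rows.append(
            {
                "participant_id": key.participant_id,
                "task": key.task,
                "pair_id": key.pair_id,
                "n_total": counts.n_total,
                "r_alt": counts.r_alt,
                "r_dim": counts.r_dim,
                "r_diag": counts.r_diag,
                "sm": sm,
            }
        )
    return pd.DataFrame(rows)


def sm_participant_means(sm_table: pd.DataFrame) -> pd.DataFrame:
    """Participant-by-task mean SM, skipping trials with undefined SM."""
    ok = sm_table.dropna(subset=["sm"])
    out = (
        ok.groupby(["participant_id", "task"], sort=True)["sm"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "sm_mean", "count": "n_trials"})
    )
    return out
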