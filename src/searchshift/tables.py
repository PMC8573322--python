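"""Readers and writers for the pipeline's delimited tables.

All tables are plain comma-delimited UTF-8 with one header row.  On disk,
probabilities are integer percents and booleans are ``True``/``False``;
in memory, probabilities are fractions (see :mod:`searchshift.gambles`).
Readers validate against a declared schema and report the first offending
row by its 1-based line number (header = line 1); unknown extra columns are
preserved untouched.  An empty file with only a header is a valid empty
table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .exceptions import SchemaError
from .gambles import Gamble, GamblePair
from .search import AOIS

__all__ = [
    "read_gamble_table",
    "write_gamble_table",
    "pairs_to_frame",
    "frame_to_pairs",
    "read_trial_table",
    "write_trial_table",
    "read_fixation_table",
    "write_fixation_table",
    "read_sm_table",
    "write_sm_table",
    "read_classification_table",
    "write_classification_table",
]


@dataclass(frozen=True)
class _Column:
    name: str
    kind: str  # "str" | "int" | "float" | "bool"
    allowed: tuple | None = None
    check: Callable[[pd.Series], pd.Series] | None = None  # boolean mask of bad rows
    required: bool = True
    allow_nan: bool = False


def _coerce(table: str, df: pd.DataFrame, col: _Column) -> pd.Series:
    s = df[col.name]
    if col.kind in ("int", "float"):
        num = pd.to_numeric(s, errors="coerce")
        bad = num.isna() & s.notna()
        if bad.any():
            row = int(bad.idxmax()) + 2
            raise SchemaError(
                f"{table}: non-numeric value {s[bad.idxmax()]!r} in column "
                f"'{col.name}' at row {row}"
            )
        if col.kind == "int":
            frac = num.dropna() % 1 != 0
            if frac.any():
                row = int(frac.idxmax()) + 2
                raise SchemaError(
                    f"{table}: non-integer value in column '{col.name}' at row {row}"
                )
            s = num.astype("int64") if not num.isna().any() else num
        else:
            s = num.astype(float)
        if not col.allow_nan and s.isna().any():
            row = int(s.isna().idxmax()) + 2
            raise SchemaError(f"{table}: missing value in column '{col.name}' at row {row}")
    elif col.kind == "bool":
        mapping = {"true": True, "false": False, "1": True, "0": False}
        vals = s.astype(str).str.strip().str.lower().map(mapping)
        if vals.isna().any():
            row = int(vals.isna().idxmax()) + 2
            raise SchemaError(
                f"{table}: invalid boolean {s[vals.isna().idxmax()]!r} in column "
                f"'{col.name}' at row {row}"
            )
        s = vals.astype(bool)
    else:
        s = s.astype(str)
    if col.allowed is not None:
        bad = ~s.isin(col.allowed)
        if bad.any():
            row = int(bad.idxmax()) + 2
            raise SchemaError(
                f"{table}: value {s[bad.idxmax()]!r} not in {col.allowed} in column "
                f"'{col.name}' at row {row}"
            )
    if col.check is not None:
        bad = col.check(s)
        if bad.any():
            row = int(bad.idxmax()) + 2
            raise SchemaError(
                f"{table}: value {s[bad.idxmax()]!r} fails range check in column "
                f"'{col.name}' at row {row}"
            )
    return s


def _read(path: str | Path, table: str, columns: list[_Column]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    df = df.reset_index(drop=True)
    for col in columns:
        if col.name not in df.columns:
            if col.required:
                raise SchemaError(f"{table}: missing required column '{col.name}'")
            continue
        df[col.name] = _coerce(table, df, col)
    return df


def _write(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


# -- gamble pairs -----------------------------------------------------------

_GAMBLE_COLS = [
    _Column("pair_id", "str"),
    _Column("outcome_a", "int", check=lambda s: (s < 1) | (s > 99)),
    _Column("prob_pct_a", "int", check=lambda s: (s < 1) | (s > 98)),
    _Column("outcome_b", "int", check=lambda s: (s < 1) | (s > 99)),
    _Column("prob_pct_b", "int", check=lambda s: (s < 1) | (s > 98)),
    _Column("risky_on_top", "bool"),
]


def pairs_to_frame(pairs: Iterable[GamblePair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pair_id": [p.pair_id for p in pairs],
            "outcome_a": [p.option_a.outcome for p in pairs],
            "prob_pct_a": [p.option_a.percent for p in pairs],
            "outcome_b": [p.option_b.outcome for p in pairs],
            "prob_pct_b": [p.option_b.percent for p in pairs],
            "risky_on_top": [p.risky_on_top for p in pairs],
        }
    )


def frame_to_pairs(df: pd.DataFrame) -> list[GamblePair]:
    return [
        GamblePair(
            str(r.pair_id),
            Gamble(int(r.outcome_a), int(r.prob_pct_a) / 100.0),
            Gamble(int(r.outcome_b), int(r.prob_pct_b) / 100.0),
            risky_on_top=bool(r.risky_on_top),
        )
        for r in df.itertuples()
    ]


def write_gamble_table(pairs: Iterable[GamblePair], path: str | Path) -> None:
    _write(pairs_to_frame(pairs), path)


def read_gamble_table(path: str | Path) -> list[GamblePair]:
    return frame_to_pairs(_read(path, "gamble table", _GAMBLE_COLS))


# -- trials -----------------------------------------------------------------

_TRIAL_COLS = [
    _Column("participant_id", "str"),
    _Column("task", "str", allowed=("ALT", "DIM")),
    _Column("pair_id", "str"),
    _Column("choice", "str", allowed=("A", "B")),
    _Column("rt_s", "float", check=lambda s: ~(s > 0)),
    _Column("task_order", "str", allowed=("ALT_FIRST", "DIM_FIRST"), required=False),
    _Column("ev_consistent", "int", required=False, check=lambda s: ~s.isin((0, 1))),
]


def read_trial_table(path: str | Path) -> pd.DataFrame:
    return _read(path, "trial table", _TRIAL_COLS)


def write_trial_table(df: pd.DataFrame, path: str | Path) -> None:
    _write(df, path)


# -- fixations --------------------------------------------------------------

_FIXATION_COLS = [
    _Column("participant_id", "str"),
    _Column("task", "str", allowed=("ALT", "DIM")),
    _Column("pair_id", "str"),
    _Column("fixation_index", "int", check=lambda s: s < 0),
    _Column("aoi", "str", allowed=AOIS),
    _Column("duration_ms", "float", check=lambda s: ~(s > 0)),
]


def read_fixation_table(path: str | Path) -> pd.DataFrame:
    return _read(path, "fixation table", _FIXATION_COLS)


def write_fixation_table(df: pd.DataFrame, path: str | Path) -> None:
    _write(df, path)


# -- SM index ---------------------------------------------------------------

_SM_COLS = [
    _Column("participant_id", "str"),
    _Column("task", "str", allowed=("ALT", "DIM")),
    _Column("pair_id", "str"),
    _Column("n_total", "int", check=lambda s: s < 0),
    _Column("r_alt", "int", check=lambda s: s < 0),
    _Column("r_dim", "int", check=lambda s: s < 0),
    _Column("r_diag", "int", check=lambda s: s < 0),
    _Column("sm", "float", allow_nan=True),
]


def read_sm_table(path: str | Path) -> pd.DataFrame:
    return _read(path, "sm table", _SM_COLS)


def write_sm_table(df: pd.DataFrame, path: str | Path) -> None:
    _write(df, path)


# -- classification ---------------------------------------------------------

_CLASSIFICATION_COLS = [
    _Column("participant_id", "str"),
    _Column("task", "str", allowed=("ALT", "DIM")),
    _Column("label", "str", allowed=("EV", "MAXIMAX", "GUESS_OR_OTHER")),
    _Column("phi_hat_ev", "float", check=lambda s: s < 0),
    _Column("g2_ev", "float", check=lambda s: s < 0),
    _Column("phi_hat_maximax", "float", check=lambda s: s < 0),
    _Column("g2_maximax", "float", check=lambda s: s < 0),
    _Column("baseline_g2", "float", check=lambda s: s < 0),
]


def read_classification_table(path: str | Path) -> pd.DataFrame:
    return _read(path, "classification table", _CLASSIFICATION_COLS)


def write_classification_table(df: pd.DataFrame, path: str | Path) -> None:
    _write(df, path)
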