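"""CSV and JSON I/O with strict schema validation.

All tables are UTF-8 CSVs with a header row. Estimates are written as
integers and the adjustment columns (s, S) with six decimals, so that
byte-level diffing of outputs from identical (config, seed) runs is
meaningful. Schema violations raise :class:`FormatError` carrying the
1-based file line number (header is line 1).
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .cohort import GENDERS, BLOCK_ORDERS
from .errors import FormatError

TRIAL_COLUMNS = ["participant_id", "school", "condition", "block_position",
                 "round", "E1", "X", "E2", "true_count"]
PARTICIPANT_COLUMNS = ["participant_id", "school", "age", "gender", "household",
                       "cohabiting_aunts_uncles", "block_order"]
CONDITIONS = ("peer", "adult")
HOUSEHOLD_VOCAB = ("nuclear", "extended", "")

_FLOAT_FMT = "%.6f"


def write_trials(trials: pd.DataFrame, path) -> None:
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path, max_round: int = 5) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != TRIAL_COLUMNS:
        raise FormatError(f"trial header must be {TRIAL_COLUMNS}", line=1)
    rows = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            block = int(row.block_position)
            rnd = int(getattr(row, "round"))
            e1, x, e2, true = (int(row.E1), int(row.X), int(row.E2), int(row.true_count))
        except ValueError:
            raise FormatError("numeric columns must be integers", line=line)
        if row.condition not in CONDITIONS:
            raise FormatError(f"condition must be one of {CONDITIONS}", line=line)
        if block not in (1, 2):
            raise FormatError("block_position must be 1 or 2", line=line)
        if not 1 <= rnd <= max_round:
            raise FormatError(f"round must lie in 1..{max_round}", line=line)
        if min(e1, x, e2, true) < 1:
            raise FormatError("estimates and true_count must be >= 1", line=line)
        if x == e1:
            raise FormatError("X must differ from E1", line=line)
        rows.append((row.participant_id, row.school, row.condition, block, rnd,
                     e1, x, e2, true))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def write_participants(participants: pd.DataFrame, path) -> None:
    participants[PARTICIPANT_COLUMNS].to_csv(path, index=False)


def read_participants(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != PARTICIPANT_COLUMNS:
        raise FormatError(f"participant header must be {PARTICIPANT_COLUMNS}", line=1)
    rows = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            age = int(row.age)
        except ValueError:
            raise FormatError("age must be an integer", line=line)
        if row.gender not in GENDERS:
            raise FormatError(f"gender must be one of {GENDERS}", line=line)
        if row.household not in HOUSEHOLD_VOCAB:
            raise FormatError(
                f"household must be one of {HOUSEHOLD_VOCAB} (empty = missing)", line=line
            )
        if row.block_order not in BLOCK_ORDERS:
            raise FormatError(f"block_order must be one of {BLOCK_ORDERS}", line=line)
        aunts = str(row.cohabiting_aunts_uncles).strip().lower()
        if aunts not in ("true", "false", "0", "1"):
            raise FormatError("cohabiting_aunts_uncles must be boolean", line=line)
        rows.append((row.participant_id, row.school, age, row.gender, row.household,
                     aunts in ("true", "1"), row.block_order))
    return pd.DataFrame(rows, columns=PARTICIPANT_COLUMNS)


def write_adjustments(adjustments: pd.DataFrame, path) -> None:
    out = adjustments.copy()
    out["s"] = out["s"].map(lambda v: _FLOAT_FMT % v)
    out.to_csv(path, index=False)


def write_summaries(summaries: pd.DataFrame, path) -> None:
    out = summaries.copy()
    for col in ("S_peer", "S_adult"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else _FLOAT_FMT % v)
    out.to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_json(payload: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonable)
        fh.write("\n")
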