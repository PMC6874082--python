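"""Measurement layer: adjustment fractions, filtering, classification.

The central statistic is the per-round adjustment

    s = (E2 - E1) / (X - E1),

the fraction of the distance from the first estimate towards the displayed
social information covered by the second estimate. Because estimates are
integers, s is an exact ratio of integer differences and the category
boundaries (s = 0 "stay", s = 1 "copy") are tested with exact equality.

A participant's social-information use in a condition is S, the mean of s
over that condition's valid rounds. Under the default ``omit`` policy the
rare contrarian (s < 0) and overshoot (s > 1) rounds are excluded, because
there the second estimate is not a weighted average of the own estimate and
the social information; ``clip`` instead maps s to the nearest value in
[0, 1] and ``include`` keeps everything.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, UndefinedAdjustmentError

CATEGORIES = ("contrarian", "stay", "compromise", "copy", "overshoot")
POLICIES = ("omit", "include", "clip")


def adjustment_s(E1: int, X: int, E2: int) -> float:
    """The adjustment fraction s = (E2 - E1) / (X - E1)."""
    if X == E1:
        raise UndefinedAdjustmentError("s undefined: X equals E1")
    return (E2 - E1) / (X - E1)


def classify(s: float) -> str:
    """Adjustment heuristic of a single round: stay (s=0), copy (s=1),
    compromise (0<s<1), contrarian (s<0) or overshoot (s>1)."""
    if not np.isfinite(s):
        raise InvalidArgumentError("s must be finite")
    if s < 0:
        return "contrarian"
    if s == 0:
        return "stay"
    if s == 1:
        return "copy"
    if s > 1:
        return "overshoot"
    return "compromise"


def _classify_array(s: np.ndarray) -> np.ndarray:
    return np.select(
        [s < 0, s == 0, s == 1, s > 1],
        ["contrarian", "stay", "copy", "overshoot"],
        default="compromise",
    )


def compute_adjustments(trials: pd.DataFrame) -> pd.DataFrame:
    """Add ``s`` and ``category`` columns to a trial table."""
    if (trials["X"] == trials["E1"]).any():
        raise UndefinedAdjustmentError("trial table contains rows with X == E1")
    out = trials.copy()
    out["s"] = (out["E2"] - out["E1"]) / (out["X"] - out["E1"])
    out["category"] = _classify_array(out["s"].to_numpy())
    return out


def filter_valid(records: pd.DataFrame, policy: str = "omit") -> pd.DataFrame:
    """Apply a validity policy to an adjustment table.

    omit    valid iff 0 <= s <= 1 (default analysis filter)
    include all rounds valid
    clip    s replaced by the nearest value in [0, 1] (categories
            recomputed), all rounds valid
    """
    if policy not in POLICIES:
        raise InvalidArgumentError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    out = records.copy()
    if policy == "omit":
        out["valid"] = (out["s"] >= 0) & (out["s"] <= 1)
    elif policy == "include":
        out["valid"] = True
    else:  # clip
        out["s"] = out["s"].clip(0.0, 1.0)
        out["category"] = _classify_array(out["s"].to_numpy())
        out["valid"] = True
    return out


def participant_summary(records: pd.DataFrame, policy: str = "omit") -> pd.DataFrame:
    """Per-participant condition means S_peer / S_adult over valid rounds.

    A condition with zero valid rounds yields NaN for S and 0 for n_valid;
    such participants contribute no row for that condition downstream.
    Accepts a table with or without prior ``valid`` flags (recomputed from
    ``policy`` if absent).
    """
    df = records if "valid" in records.columns else filter_valid(records, policy)
    out = []
    for pid, grp in df.groupby("participant_id", sort=True):
        row = {"participant_id": pid}
        for condition in ("peer", "adult"):
            sub = grp[(grp["condition"] == condition) & grp["valid"]]
            row[f"S_{condition}"] = sub["s"].mean() if len(sub) else np.nan
            row[f"n_valid_{condition}"] = int(len(sub))
        out.append(row)
    return pd.DataFrame(
        out, columns=["participant_id", "S_peer", "S_adult", "n_valid_peer", "n_valid_adult"]
    )


def predicted_second_estimate(E1: int, X: int, S: float) -> float:
    """Predicted second estimate E2 = (1 - S) E1 + S X for S in [0, 1]."""
    if not 0 <= S <= 1:
        raise InvalidArgumentError("S must lie in [0, 1]")
    return (1.0 - S) * E1 + S * X


def heuristic_frequencies(records: pd.DataFrame, pooling: str = "all_rounds") -> pd.Series:
    """Proportion of rounds in each adjustment category.

    ``all_rounds`` divides by every classified round; ``valid_rounds``
    restricts numerator and denominator to rounds with 0 <= s <= 1. Both
    denominators are exposed because published category percentages are
    often reported against mixed denominators.
    """
    if len(records) == 0:
        raise InvalidArgumentError("empty adjustment table")
    if pooling == "all_rounds":
        sub = records
    elif pooling == "valid_rounds":
        sub = records[(records["s"] >= 0) & (records["s"] <= 1)]
    else:
        raise InvalidArgumentError(f"unknown pooling {pooling!r}")
    counts = sub["category"].value_counts()
    denom = len(sub)
    return pd.Series(
        {c: counts.get(c, 0) / denom if denom else np.nan for c in CATEGORIES},
        name="proportion",
    )


def deviation_table(trials: pd.DataFrame, signed: bool = False) -> pd.DataFrame:
    """Long table of estimate deviations from the true count.

    Two rows per trial (period "first" for E1, "second" for E2) with the
    absolute deviation by default; ``signed=True`` keeps the sign. Feeds the
    accuracy mixed model.
    """
    base = trials[["participant_id", "school", "condition", "round", "true_count"]]
    parts = []
    for period, col in (("first", "E1"), ("second", "E2")):
        dev = trials[col] - trials["true_count"]
        if not signed:
            dev = dev.abs()
        part = base.copy()
        part["period"] = period
        part["deviation"] = dev.to_numpy()
        parts.append(part)
    out = pd.concat(parts, ignore_index=True)
    return out.drop(columns=["true_count"])
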