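"""The pre-recorded estimate bank.

The displayed social information comes from a fixed pool of first estimates
produced earlier by 24 adults and 14 students who did the task without
social information, each completing 6 iterations of the 5 rounds — hence
144 adult and 84 student estimates per round. The bank here is a generative
stand-in built from the same first-estimate model as the cohort; only the
construction counts of the original pool are reproducible, not its
distributions. Sampling from the bank is non-consuming: the same value may
be shown to many participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behaviour import AgentParams, first_estimate
from .errors import FormatError, InvalidArgumentError
from .task import StimulusSpec

SOURCE_TYPES = ("adult", "student")


@dataclass
class EstimateBank:
    """Multisets of positive integer estimates keyed by (round, source)."""

    entries: dict[tuple[int, str], np.ndarray]
    provenance: str = "simulated"
    schedule: list[StimulusSpec] | None = None

    @property
    def rounds(self) -> list[int]:
        return sorted({r for (r, _) in self.entries})

    def candidates(self, round_index: int, source_type: str) -> np.ndarray:
        key = (int(round_index), source_type)
        if key not in self.entries:
            raise InvalidArgumentError(
                f"bank has no entries for round {round_index}, source {source_type!r}"
            )
        return self.entries[key]

    def counts(self, round_index: int) -> tuple[int, int]:
        """(n_adult, n_student) entry counts for one round."""
        if round_index not in self.rounds:
            raise InvalidArgumentError(f"unknown round {round_index}")
        n_adult = len(self.entries.get((round_index, "adult"), ()))
        n_student = len(self.entries.get((round_index, "student"), ()))
        return n_adult, n_student


def build_bank(
    schedule: list[StimulusSpec],
    n_adults: int = 24,
    n_students: int = 14,
    n_iterations: int = 6,
    estimation_params: AgentParams | None = None,
    seed: int = 0,
) -> EstimateBank:
    """Simulate the pre-recorded sample.

    Each bank member produces one first estimate per round per iteration,
    with no social information and no feedback; iterations are independent
    draws. Adult and student members use the same first-estimate model by
    default (pass a different ``estimation_params`` to change both; the
    original study gave participants no information about source skill and
    reported no accuracy difference).
    """
    if n_adults < 0 or n_students < 0:
        raise InvalidArgumentError("member counts must be non-negative")
    if n_iterations < 1:
        raise InvalidArgumentError("n_iterations must be >= 1")
    if n_adults + n_students == 0:
        raise InvalidArgumentError("bank needs at least one member")
    params = estimation_params or AgentParams()
    rng = np.random.default_rng(seed)
    entries: dict[tuple[int, str], np.ndarray] = {}
    for source, n_members in (("adult", n_adults), ("student", n_students)):
        per_round: dict[int, list[int]] = {spec.round_index: [] for spec in schedule}
        for _member in range(n_members):
            for _iteration in range(n_iterations):
                for spec in schedule:
                    per_round[spec.round_index].append(
                        first_estimate(spec.true_count, params, rng)
                    )
        for r, values in per_round.items():
            entries[(r, source)] = np.asarray(values, dtype=int)
    return EstimateBank(entries=entries, provenance="simulated", schedule=list(schedule))


def bank_counts(bank: EstimateBank, round_index: int) -> tuple[int, int]:
    """(n_adult, n_student) for one round of the bank."""
    return bank.counts(round_index)


def save_bank(bank: EstimateBank, path) -> None:
    """Serialise the bank as a CSV with columns round, source_type, estimate."""
    rows = []
    for (r, source) in sorted(bank.entries):
        for v in bank.entries[(r, source)]:
            rows.append((r, source, int(v)))
    pd.DataFrame(rows, columns=["round", "source_type", "estimate"]).to_csv(
        path, index=False
    )


def load_bank(path) -> EstimateBank:
    """Load a bank CSV, validating every row (schema errors carry the 1-based
    file line number, header included)."""
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # pragma: no cover - passthrough
        raise FormatError(f"cannot read bank file: {exc}") from exc
    expected = ["round", "source_type", "estimate"]
    if list(df.columns) != expected:
        raise FormatError(f"bank header must be {expected}, got {list(df.columns)}", line=1)
    entries: dict[tuple[int, str], list[int]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            r = int(row.round)
            est = int(row.estimate)
        except (TypeError, ValueError):
            raise FormatError("round and estimate must be integers", line=line)
        if r < 1:
            raise FormatError(f"round must be >= 1, got {r}", line=line)
        if row.source_type not in SOURCE_TYPES:
            raise FormatError(
                f"source_type must be one of {SOURCE_TYPES}, got {row.source_type!r}",
                line=line,
            )
        if est < 1:
            raise FormatError(f"estimate must be >= 1, got {est}", line=line)
        entries.setdefault((r, row.source_type), []).append(est)
    return EstimateBank(
        entries={k: np.asarray(v, dtype=int) for k, v in entries.items()},
        provenance="loaded",
        schedule=None,
    )
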