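"""The estimation-task engine.

Implements the experimental algorithm of a BEAST-style session: a schedule
of numerosity stimuli (images with 50-60 animals, a different species each
round), a per-round relative displacement Δ that places a "target" value of
social information 15-25% away from the participant's first estimate in the
direction of the true count, nearest-value selection of the displayed value
from a pre-recorded estimate bank, and the points/bonus payoff rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .behaviour import AgentParams, first_estimate, second_estimate
from .errors import InvalidArgumentError, NoValidSocialInfoError

#: Default per-round relative displacement of the social-information target.
DEFAULT_DELTAS = (0.25, 0.15, 0.20, 0.15, 0.25)

#: Condition -> source type of the displayed estimate.
CONDITION_SOURCE = {"peer": "student", "adult": "adult"}

_SPECIES = (
    "ants", "bees", "butterflies", "cranes", "deer", "dolphins",
    "fish", "flamingos", "frogs", "geese", "gulls", "sheep",
)


@dataclass(frozen=True)
class StimulusSpec:
    """One round's stimulus: an image with a known number of animals."""

    round_index: int
    true_count: int
    display_seconds: float = 6.0
    species_label: str = ""

    def __post_init__(self):
        if self.round_index < 1:
            raise InvalidArgumentError("round_index must be >= 1")
        if self.true_count < 1:
            raise InvalidArgumentError("true_count must be >= 1")


@dataclass(frozen=True)
class DeltaSchedule:
    """Ordered per-round relative displacements, each in [0.15, 0.25]."""

    deltas: tuple[float, ...] = DEFAULT_DELTAS

    def __post_init__(self):
        object.__setattr__(self, "deltas", tuple(float(d) for d in self.deltas))
        if any(not (0.15 <= d <= 0.25) for d in self.deltas):
            raise InvalidArgumentError("every delta must lie in [0.15, 0.25]")

    def for_round(self, round_index: int) -> float:
        if not 1 <= round_index <= len(self.deltas):
            raise InvalidArgumentError(
                f"round_index {round_index} outside schedule of length {len(self.deltas)}"
            )
        return self.deltas[round_index - 1]


@dataclass
class TrialRecord:
    """One round of one participant in one condition."""

    participant_id: str
    condition: str
    block_position: int
    round_index: int
    E1: int
    X: int
    E2: int
    true_count: int


@dataclass(frozen=True)
class PayoffResult:
    points: int
    bonus_items: int
    total_items: int


def make_stimulus_schedule(
    seed: int,
    n_rounds: int = 5,
    true_count_min: int = 50,
    true_count_max: int = 60,
) -> list[StimulusSpec]:
    """Generate a stimulus schedule with uniform true counts in [min, max].

    Species labels are cosmetic and distinct across rounds (a different
    species per round prevents image memory); they have no behavioural
    effect.
    """
    if n_rounds < 1:
        raise InvalidArgumentError("n_rounds must be >= 1")
    if not 1 <= true_count_min <= true_count_max:
        raise InvalidArgumentError("need 1 <= true_count_min <= true_count_max")
    rng = np.random.default_rng(seed)
    counts = rng.integers(true_count_min, true_count_max + 1, size=n_rounds)
    if n_rounds <= len(_SPECIES):
        labels = list(rng.choice(_SPECIES, size=n_rounds, replace=False))
    else:
        labels = [f"species-{i}" for i in range(1, n_rounds + 1)]
    return [
        StimulusSpec(round_index=i + 1, true_count=int(counts[i]), species_label=str(labels[i]))
        for i in range(n_rounds)
    ]


def target_social_value(
    E1: int, true_count: int, delta: float, rng: np.random.Generator | None = None
) -> float:
    """Compute the target social-information value X' = E1 (1 ± Δ).

    The displacement points towards the true count: ``E1 (1 + Δ)`` when the
    first estimate is below truth, ``E1 (1 - Δ)`` above it. At ``E1 ==
    true_count`` a fair coin from ``rng`` decides the direction. X' is kept
    real valued; integer snapping happens when the bank value is selected.
    """
    if E1 < 1:
        raise InvalidArgumentError("E1 must be >= 1")
    if not 0 < delta < 1:
        raise InvalidArgumentError("delta must lie in (0, 1)")
    if E1 < true_count:
        return E1 * (1.0 + delta)
    if E1 > true_count:
        return E1 * (1.0 - delta)
    if rng is None:
        raise InvalidArgumentError("rng required for the coin flip when E1 == true_count")
    return E1 * (1.0 + delta) if rng.random() < 0.5 else E1 * (1.0 - delta)


def select_social_info(
    E1: int,
    true_count: int,
    delta: float,
    candidates,
    rng: np.random.Generator,
) -> int:
    """Select the displayed value X: the bank candidate nearest to X'.

    Candidates equal to E1 are excluded first so that the adjustment
    fraction s = (E2-E1)/(X-E1) is always defined. Exact distance ties are
    broken by a seeded uniform draw among the tied values.
    """
    xprime = target_social_value(E1, true_count, delta, rng)
    cands = np.asarray(list(candidates), dtype=int)
    cands = cands[cands != E1]
    if cands.size == 0:
        raise NoValidSocialInfoError(
            f"no candidate differs from E1={E1}; cannot display social information"
        )
    dist = np.abs(cands - xprime)
    tied = np.unique(cands[dist == dist.min()])
    if tied.size == 1:
        return int(tied[0])
    return int(rng.choice(tied))


def payoff(estimate: int, true_count: int) -> int:
    """Points for one estimate: 100 minus 5 per animal of error, floored at 0."""
    if estimate < 1 or true_count < 1:
        raise InvalidArgumentError("estimate and true_count must be >= 1")
    return int(max(0, 100 - 5 * abs(int(estimate) - int(true_count))))


def bonus_items(points: int) -> PayoffResult:
    """Convert points to items: one bonus item per completed 20 points,
    plus the two participation items everyone receives."""
    if not 0 <= points <= 100:
        raise InvalidArgumentError("points must lie in [0, 100]")
    bonus = int(points) // 20
    return PayoffResult(points=int(points), bonus_items=bonus, total_items=bonus + 2)


def run_session(
    profile,
    params: AgentParams,
    bank,
    schedule: list[StimulusSpec],
    deltas: DeltaSchedule,
    seed: int,
) -> list[TrialRecord]:
    """Simulate one participant's full session: two blocks of five rounds.

    The block order (peer first or adult first) comes from the profile's
    counterbalancing assignment. Within each round the agent produces E1,
    the engine computes X' with the round's Δ and snaps it to the nearest
    bank value, and the agent produces E2. No feedback is given, so no state
    is carried between rounds.
    """
    rng = np.random.default_rng(seed)
    if getattr(profile, "block_order", "peer_first") == "peer_first":
        order = ("peer", "adult")
    else:
        order = ("adult", "peer")
    household = getattr(profile, "household", None) or "nuclear"
    age = float(getattr(profile, "age", 13))
    records: list[TrialRecord] = []
    for block_position, condition in enumerate(order, start=1):
        source = CONDITION_SOURCE[condition]
        for spec in schedule:
            e1 = first_estimate(spec.true_count, params, rng)
            delta = deltas.for_round(spec.round_index)
            x = select_social_info(
                e1, spec.true_count, delta, bank.candidates(spec.round_index, source), rng
            )
            e2 = second_estimate(
                e1, x, condition, params, rng, household=household, age=age
            )
            records.append(
                TrialRecord(
                    participant_id=getattr(profile, "participant_id", "P?"),
                    condition=condition,
                    block_position=block_position,
                    round_index=spec.round_index,
                    E1=e1,
                    X=x,
                    E2=e2,
                    true_count=spec.true_count,
                )
            )
    return records
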