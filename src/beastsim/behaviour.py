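"""Generative behaviour model for estimation agents.

Two pieces of agent behaviour are modelled:

* **First estimates.** Numerosity estimates of a briefly shown group of
  animals are noisy and, on average, about 10% below the true count — the
  usual underestimation in rapid numerosity judgements. We model
  ``E1 = round(true_count * exp(z))`` with ``z ~ Normal(bias_mu, bias_sigma)``.
  The default ``bias_mu = ln(0.9) - bias_sigma**2 / 2`` makes the expected
  ratio ``E[E1/true]`` exactly 0.90.

* **Second estimates.** After seeing another person's estimate ``X``, the
  agent covers a fraction ``s`` of the distance from its own first estimate
  towards ``X``.  The fraction is drawn from a five-component heuristic
  mixture: *stay* (s = 0), *copy* (s = 1), *compromise* (0 < s < 1, a Beta
  law), plus the rare *contrarian* (s < 0) and *overshoot* (s > 1) moves.
  Mixture weights are condition specific: social information sourced from an
  adult is copied more and ignored less than information from a peer, which
  is what produces the adult > peer difference in mean adjustment.

The analytic mixture expectations in :meth:`AgentParams.expected_adjustment`
serve as the recovery oracle for the whole simulation pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

CONDITIONS = ("peer", "adult")
HOUSEHOLDS = ("nuclear", "extended")


@dataclass(frozen=True)
class MixtureWeights:
    """Probabilities of the four non-compromise heuristics; the remainder
    of the unit mass is the compromise component."""

    p_stay: float
    p_copy: float
    p_contrarian: float
    p_overshoot: float

    def __post_init__(self):
        probs = (self.p_stay, self.p_copy, self.p_contrarian, self.p_overshoot)
        if any(p < 0 for p in probs):
            raise InvalidArgumentError("mixture probabilities must be non-negative")
        if sum(probs) > 1.0 + 1e-12:
            raise InvalidArgumentError("mixture probabilities must sum to at most 1")

    @property
    def p_compromise(self) -> float:
        return 1.0 - (self.p_stay + self.p_copy + self.p_contrarian + self.p_overshoot)


# Calibrated so that the filtered (0 <= s <= 1) mixture means are 43.7% in
# the peer condition and 47.5% in the adult condition, with contrarian and
# overshoot rates of 2.2% and 5.6% of all rounds, and with staying more
# common towards peers and copying more common towards adults.
DEFAULT_PEER_WEIGHTS = MixtureWeights(0.315, 0.135, 0.022, 0.056)
DEFAULT_ADULT_WEIGHTS = MixtureWeights(0.280, 0.170, 0.022, 0.056)

_DEFAULT_SIGMA = 0.15


@dataclass(frozen=True)
class AgentParams:
    """Parameters of the generative agent.

    Parameters
    ----------
    bias_mu, bias_sigma : float
        Location and scale of the log-ratio ``ln(E1/true_count)``. Defaults
        give a mean ratio of exactly 0.90 (10% underestimation) with ~15%
        dispersion.
    peer_weights, adult_weights : MixtureWeights
        Heuristic mixture per condition.
    compromise_shape : (float, float)
        Beta shape parameters (a, b) of the compromise fraction on (0, 1).
    adult_shift : float
        Additive shift of the compromise-component mean in the adult
        condition, on top of the weight differences. Default 0.
    household_shift : float
        Additive shift of the compromise mean for agents from extended
        households. Default 0 — the null under which the household
        interaction is calibrated.
    age_coef : float
        Optional linear effect of (age - 13) years on the compromise mean.
        Default 0: age affects nothing.
    contrarian_s, overshoot_s : float
        Fixed magnitudes of the two discarded move types.
    """

    bias_mu: float = math.log(0.9) - 0.5 * _DEFAULT_SIGMA**2
    bias_sigma: float = _DEFAULT_SIGMA
    peer_weights: MixtureWeights = field(default=DEFAULT_PEER_WEIGHTS)
    adult_weights: MixtureWeights = field(default=DEFAULT_ADULT_WEIGHTS)
    compromise_shape: tuple[float, float] = (1.9866, 1.5134)
    adult_shift: float = 0.0
    household_shift: float = 0.0
    age_coef: float = 0.0
    contrarian_s: float = -0.2
    overshoot_s: float = 1.2

    def __post_init__(self):
        a, b = self.compromise_shape
        if a <= 0 or b <= 0:
            raise InvalidArgumentError("compromise_shape entries must be positive")
        if self.bias_sigma < 0:
            raise InvalidArgumentError("bias_sigma must be non-negative")

    def weights(self, condition: str) -> MixtureWeights:
        if condition == "peer":
            return self.peer_weights
        if condition == "adult":
            return self.adult_weights
        raise InvalidArgumentError(f"unknown condition {condition!r}")

    def compromise_mean(
        self, condition: str, household: str = "nuclear", age: float = 13.0
    ) -> float:
        """Mean of the compromise fraction after condition/household/age shifts."""
        a, b = self.compromise_shape
        mu = a / (a + b)
        if condition == "adult":
            mu += self.adult_shift
        if household == "extended":
            mu += self.household_shift
        mu += self.age_coef * (age - 13.0)
        return float(np.clip(mu, 0.02, 0.98))

    def expected_adjustment(
        self,
        condition: str,
        household: str = "nuclear",
        age: float = 13.0,
        filtered: bool = True,
    ) -> float:
        """Analytic expectation of the adjustment fraction s.

        ``filtered=True`` conditions on 0 <= s <= 1 (the default analysis
        filter); otherwise all five components contribute.
        """
        w = self.weights(condition)
        mu = self.compromise_mean(condition, household, age)
        core = w.p_copy * 1.0 + w.p_compromise * mu
        if filtered:
            return core / (w.p_stay + w.p_copy + w.p_compromise)
        return core + w.p_contrarian * self.contrarian_s + w.p_overshoot * self.overshoot_s


def first_estimate(true_count: int, params: AgentParams, rng: np.random.Generator) -> int:
    """Draw a first estimate for an image with ``true_count`` animals.

    Returns a positive integer; the floor at 1 only binds for extreme
    negative noise draws.
    """
    if true_count < 1:
        raise InvalidArgumentError("true_count must be >= 1")
    z = rng.normal(params.bias_mu, params.bias_sigma)
    return max(1, int(np.rint(true_count * math.exp(z))))


def second_estimate(
    E1: int,
    X: int,
    condition: str,
    params: AgentParams,
    rng: np.random.Generator,
    household: str = "nuclear",
    age: float = 13.0,
) -> int:
    """Draw a second estimate given first estimate ``E1`` and social info ``X``.

    A heuristic is drawn from the condition-specific mixture; the intended
    fraction ``s*`` is realised as ``E2 = round(E1 + s* (X - E1))``, clamped
    to >= 1. Rounding to integer estimates means the recomputed s can differ
    from ``s*`` by up to ``0.5/|X - E1|``.
    """
    if X == E1:
        raise InvalidArgumentError("X must differ from E1")
    w = params.weights(condition)
    u = rng.random()
    if u < w.p_stay:
        s = 0.0
    elif u < w.p_stay + w.p_copy:
        s = 1.0
    elif u < w.p_stay + w.p_copy + w.p_contrarian:
        s = params.contrarian_s
    elif u < w.p_stay + w.p_copy + w.p_contrarian + w.p_overshoot:
        s = params.overshoot_s
    else:
        mu = params.compromise_mean(condition, household, age)
        kappa = sum(params.compromise_shape)
        s = rng.beta(mu * kappa, (1.0 - mu) * kappa)
    return max(1, int(np.rint(E1 + s * (X - E1))))
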