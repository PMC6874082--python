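"""Statistical layer: paired comparison, mixed models, recovery harness.

Model objects follow the statsmodels idiom: build a model from a data frame
(``from_tables`` joins the pipeline's tables into the model frame), call
``fit()`` and get a results object carrying the coefficient table, random
effect variances and a ``summary()`` string.

Four models are provided:

* :class:`AdjustmentModel` — linear mixed model for the condition-level
  mean adjustment S (two rows per participant), fixed effects model_type,
  household_type, their interaction, gender and age, with random intercepts
  for school and for participant nested in school.
* :class:`StayModel` / :class:`CopyModel` — logistic mixed models for the
  round-level binary decisions to stay with the first estimate (s = 0) or
  to copy the social information (s = 1), same fixed/random structure.
* :class:`AccuracyModel` — linear mixed model comparing absolute deviations
  from the true count between first and second estimates, with period
  nested in participant nested in school as random effects.

Predictor coding throughout: model_type peer=0/adult=1; household
nuclear=0/extended=1; gender male=0/female=1; age in years centered at 13
(so intercepts refer to a 13-year-old male from a nuclear household seeing
peer information; slopes are per year and unaffected by the centering).

Coefficient p-values are Wald tests on the normal approximation for the
linear mixed models; the logistic models are fitted by Laplace/MAP
approximation (statsmodels' Bayesian mixed GLM with flat-ish priors),
whose posterior mode and curvature-based sd agree closely with
lme4-style ML fits (see docs/methods.md). With only two schools the school-level
variance is weakly identified; a zero/boundary school component is
tolerated and reported, and ``include_school=False`` drops it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

from .bank import build_bank
from .behaviour import AgentParams
from .cohort import CohortConfig, profiles_to_frame, sample_cohort, simulate_experiment
from .errors import InsufficientDataError, InvalidArgumentError
from .metrics import (
    compute_adjustments,
    filter_valid,
    heuristic_frequencies,
    participant_summary,
)
from .seeds import child_seed
from .task import DeltaSchedule, make_stimulus_schedule

FE_TERMS = ("intercept", "model_type", "household_type",
            "model_type:household_type", "gender", "age")

_RENAME = {"Intercept": "intercept"}

_FORMULA = "{y} ~ model_type + household_type + model_type:household_type + gender + age"


# ---------------------------------------------------------------------------
# Paired comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedTestResult:
    """Classic paired t-test of S_adult - S_peer over complete pairs."""

    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    cohens_d: float
    mean_peer: float
    mean_adult: float
    n_pairs: int
    degenerate: bool = False

    def summary(self) -> str:
        lines = [
            "Paired t-test on per-participant mean adjustment (S_adult - S_peer)",
            f"  n pairs      : {self.n_pairs}",
            f"  mean S_peer  : {self.mean_peer:.4f}",
            f"  mean S_adult : {self.mean_adult:.4f}",
            f"  t = {self.t_statistic:.4f}, d.f. = {self.degrees_of_freedom}, "
            f"p = {self.p_value:.4g}, Cohen's d = {self.cohens_d:.4f}",
        ]
        if self.degenerate:
            lines.append("  note: zero variance of differences (degenerate)")
        return "\n".join(lines)


def paired_test(summaries: pd.DataFrame) -> PairedTestResult:
    """Paired t-test comparing S_peer and S_adult distributions.

    Participants lacking either condition mean are dropped (pairwise
    completeness), so d.f. = complete pairs - 1. The difference is taken as
    S_adult - S_peer, so a positive t means stronger adjustment towards
    adults. Cohen's d is the paired version: mean difference over the sd of
    the differences.
    """
    pairs = summaries.dropna(subset=["S_peer", "S_adult"])
    n = len(pairs)
    if n < 2:
        raise InsufficientDataError("need at least 2 complete S_peer/S_adult pairs")
    diff = (pairs["S_adult"] - pairs["S_peer"]).to_numpy()
    sd = diff.std(ddof=1)
    if sd == 0:
        return PairedTestResult(
            t_statistic=0.0, degrees_of_freedom=n - 1, p_value=1.0, cohens_d=0.0,
            mean_peer=float(pairs["S_peer"].mean()),
            mean_adult=float(pairs["S_adult"].mean()),
            n_pairs=n, degenerate=True,
        )
    res = st.ttest_rel(pairs["S_adult"], pairs["S_peer"])
    return PairedTestResult(
        t_statistic=float(res.statistic),
        degrees_of_freedom=n - 1,
        p_value=float(res.pvalue),
        cohens_d=float(diff.mean() / sd),
        mean_peer=float(pairs["S_peer"].mean()),
        mean_adult=float(pairs["S_adult"].mean()),
        n_pairs=n,
    )


# ---------------------------------------------------------------------------
# Mixed-model results container
# ---------------------------------------------------------------------------

@dataclass
class MixedFitResult:
    """Coefficient table plus bookkeeping for one fitted model."""

    model_name: str
    params: pd.DataFrame  # index: term; columns: estimate, se, z, p
    n_observations: int
    n_participants: int
    random_effect_variances: dict[str, float]
    converged: bool = True
    method: str = ""
    warnings: list[str] = field(default_factory=list)

    def coef(self, term: str) -> float:
        return float(self.params.loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.params.loc[term, "se"])

    def pvalue(self, term: str) -> float:
        return float(self.params.loc[term, "p"])

    def summary(self) -> str:
        lines = [f"{self.model_name} ({self.method})"]
        lines.append(f"  n = {self.n_observations}, N participants = {self.n_participants}")
        with pd.option_context("display.float_format", "{:0.4f}".format):
            lines.append(self.params.to_string())
        for name, var in self.random_effect_variances.items():
            lines.append(f"  var({name}) = {var:.5f}")
        if not self.converged:
            lines.append("  WARNING: fit did not converge / degenerate")
        for w in self.warnings:
            lines.append(f"  note: {w}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "coefficients": {
                term: {
                    "estimate": float(row["estimate"]),
                    "se": float(row["se"]),
                    "p": float(row["p"]),
                }
                for term, row in self.params.iterrows()
            },
            "n_observations": int(self.n_observations),
            "n_participants": int(self.n_participants),
            "random_effect_variances": {
                k: float(v) for k, v in self.random_effect_variances.items()
            },
            "converged": bool(self.converged),
            "method": self.method,
            "warnings": list(self.warnings),
        }


def _code_profiles(prof: pd.DataFrame, household_definition: str) -> pd.DataFrame:
    out = prof.copy()
    if household_definition == "grandparents":
        hh = out["household"]
    elif household_definition == "grandparents_or_aunts_uncles":
        extended = (out["household"] == "extended") | out[
            "cohabiting_aunts_uncles"
        ].astype(bool)
        hh = np.where(out["household"] == "", "", np.where(extended, "extended", "nuclear"))
        hh = pd.Series(hh, index=out.index)
    else:
        raise InvalidArgumentError(f"unknown household definition {household_definition!r}")
    out["household_type"] = hh.map({"extended": 1, "nuclear": 0})
    out["gender"] = out["gender"].map({"male": 0, "female": 1})
    # centering age stabilises the mixed-model fits; slopes are unchanged
    out["age"] = out["age"].astype(float) - 13.0
    return out[["participant_id", "school", "household_type", "gender", "age"]]


def _as_profile_frame(profiles) -> pd.DataFrame:
    if isinstance(profiles, pd.DataFrame):
        return profiles
    return profiles_to_frame(profiles)


# ---------------------------------------------------------------------------
# Model 1: linear mixed model on condition-level S
# ---------------------------------------------------------------------------

class AdjustmentModel:
    """Linear mixed model for participants' mean adjustment S.

    The model frame has up to two rows per participant (peer and adult
    condition means); rows with an undefined S (no valid rounds in that
    condition) are dropped, so n can fall below twice the number of
    participants.
    """

    def __init__(self, data: pd.DataFrame, include_school: bool = True,
                 random_effects: bool = True):
        required = {"S", "model_type", "household_type", "gender", "age",
                    "participant_id", "school"}
        missing = required - set(data.columns)
        if missing:
            raise InvalidArgumentError(f"model frame lacks columns {sorted(missing)}")
        self.data = data.dropna(subset=["S", "household_type"]).reset_index(drop=True)
        self.include_school = include_school
        self.random_effects = random_effects

    @classmethod
    def from_tables(cls, summaries: pd.DataFrame, profiles,
                    household_definition: str = "grandparents", **kwargs) -> "AdjustmentModel":
        prof = _code_profiles(_as_profile_frame(profiles), household_definition)
        merged = summaries.merge(prof, on="participant_id", how="inner")
        rows = []
        for condition, code in (("peer", 0), ("adult", 1)):
            sub = merged[merged[f"n_valid_{condition}"] > 0].copy()
            sub["S"] = sub[f"S_{condition}"]
            sub["model_type"] = code
            rows.append(sub[["participant_id", "school", "S", "model_type",
                             "household_type", "gender", "age"]])
        data = pd.concat(rows, ignore_index=True)
        return cls(data, **kwargs)

    def fit(self, reml: bool = True) -> MixedFitResult:
        df = self.data
        if not self.random_effects:
            res = smf.ols(_FORMULA.format(y="S"), data=df).fit()
            table = pd.DataFrame(
                {
                    "estimate": res.params.rename(index=_RENAME),
                    "se": res.bse.rename(index=_RENAME),
                    "z": res.tvalues.rename(index=_RENAME),
                    "p": res.pvalues.rename(index=_RENAME),
                }
            )
            return MixedFitResult(
                model_name="adjustment (OLS, no random effects)",
                params=table,
                n_observations=int(res.nobs),
                n_participants=df["participant_id"].nunique(),
                random_effect_variances={"residual": float(res.mse_resid)},
                converged=True,
                method="OLS",
            )
        caught: list[str] = []
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            if self.include_school:
                md = sm.MixedLM.from_formula(
                    _FORMULA.format(y="S"),
                    groups="school",
                    re_formula="1",
                    vc_formula={"participant": "0 + C(participant_id)"},
                    data=df,
                )
            else:
                md = sm.MixedLM.from_formula(
                    _FORMULA.format(y="S"), groups="participant_id", data=df
                )
            try:
                res = md.fit(reml=reml, method="lbfgs", maxiter=500)
            except Exception:
                res = md.fit(reml=reml, method="powell", maxiter=1000)
            caught = sorted({str(w.message) for w in wlist})
        fe = res.fe_params
        se = res.bse[fe.index]
        z = fe / se
        p = 2 * st.norm.sf(np.abs(z))
        table = pd.DataFrame(
            {"estimate": fe, "se": se, "z": z, "p": p}
        ).rename(index=_RENAME)
        variances = {"residual": float(res.scale)}
        if self.include_school:
            variances["school"] = float(np.asarray(res.cov_re)[0, 0])
            variances["participant(school)"] = float(np.asarray(res.vcomp).ravel()[0])
        else:
            variances["participant"] = float(np.asarray(res.cov_re)[0, 0])
        return MixedFitResult(
            model_name="adjustment (LMM)",
            params=table,
            n_observations=len(df),
            n_participants=df["participant_id"].nunique(),
            random_effect_variances=variances,
            converged=bool(getattr(res, "converged", True)),
            method="MixedLM " + ("REML" if reml else "ML") + ", Wald z",
            warnings=caught,
        )


# ---------------------------------------------------------------------------
# Models 2-3: logistic mixed models on round-level stay / copy
# ---------------------------------------------------------------------------

class _BinaryHeuristicModel:
    """Shared machinery for the stay/copy logistic mixed models."""

    outcome: str = ""
    target_value: float = np.nan

    def __init__(self, data: pd.DataFrame, include_school: bool = True):
        required = {"y", "model_type", "household_type", "gender", "age",
                    "participant_id", "school"}
        missing = required - set(data.columns)
        if missing:
            raise InvalidArgumentError(f"model frame lacks columns {sorted(missing)}")
        self.data = data.dropna(subset=["y", "household_type"]).reset_index(drop=True)
        self.include_school = include_school

    @classmethod
    def from_tables(cls, adjustments: pd.DataFrame, profiles,
                    rounds: str = "filtered",
                    household_definition: str = "grandparents", **kwargs):
        """Build the round-level model frame.

        ``rounds='filtered'`` (default) defines the outcome on rounds with
        0 <= s <= 1; ``rounds='all'`` keeps every defined round.
        """
        if rounds == "filtered":
            sub = adjustments[(adjustments["s"] >= 0) & (adjustments["s"] <= 1)].copy()
        elif rounds == "all":
            sub = adjustments.copy()
        else:
            raise InvalidArgumentError(f"unknown rounds option {rounds!r}")
        prof = _code_profiles(_as_profile_frame(profiles), household_definition)
        sub["y"] = (sub["s"] == cls.target_value).astype(int)
        sub["model_type"] = sub["condition"].map({"peer": 0, "adult": 1})
        merged = sub.merge(
            prof.drop(columns=["school"]), on="participant_id", how="inner"
        )
        data = merged[["participant_id", "school", "y", "model_type",
                       "household_type", "gender", "age"]]
        return cls(data, **kwargs)

    def fit(self, method: str = "map") -> MixedFitResult:
        """Fit the logistic mixed model.

        ``method='map'`` (default) uses the Laplace/MAP approximation whose
        standard errors match likelihood-based GLMM fits; ``'vb'`` is the
        faster mean-field variational fit, which understates SEs.
        """
        df = self.data
        name = f"{self.outcome} (logistic GLMM)"
        if df["y"].nunique() < 2:
            table = pd.DataFrame(
                np.nan, index=list(FE_TERMS), columns=["estimate", "se", "z", "p"]
            )
            return MixedFitResult(
                model_name=name,
                params=table,
                n_observations=len(df),
                n_participants=df["participant_id"].nunique(),
                random_effect_variances={},
                converged=False,
                method="degenerate outcome",
                warnings=[f"outcome '{self.outcome}' is constant; no fit attempted"],
            )
        vc = {"participant": "0 + C(participant_id)"}
        if self.include_school:
            vc["school"] = "0 + C(school)"
        caught: list[str] = []
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            md = BinomialBayesMixedGLM.from_formula(
                _FORMULA.format(y="y"), vc, df
            )
            res = md.fit_map() if method == "map" else md.fit_vb()
            caught = sorted({str(w.message) for w in wlist})
        fe_names = list(md.fep_names)
        est = np.asarray(res.fe_mean)
        se = np.asarray(res.fe_sd)
        z = est / se
        p = 2 * st.norm.sf(np.abs(z))
        table = pd.DataFrame(
            {"estimate": est, "se": se, "z": z, "p": p}, index=fe_names
        ).rename(index=_RENAME)
        # vcp parameters are log standard deviations of the components
        variances = {
            nm: float(np.exp(2.0 * m))
            for nm, m in zip(md.vcp_names, np.asarray(res.vcp_mean))
        }
        return MixedFitResult(
            model_name=name,
            params=table,
            n_observations=len(df),
            n_participants=df["participant_id"].nunique(),
            random_effect_variances=variances,
            converged=True,
            method=("Laplace MAP" if method == "map" else "variational Bayes")
            + " logistic mixed model, normal-approx p",
            warnings=caught,
        )


class StayModel(_BinaryHeuristicModel):
    """Logistic mixed model for the decision to stay (s = 0)."""

    outcome = "stay"
    target_value = 0.0


class CopyModel(_BinaryHeuristicModel):
    """Logistic mixed model for the decision to copy (s = 1)."""

    outcome = "copy"
    target_value = 1.0


def fit_stay_glmm(adjustments, profiles, **kwargs) -> MixedFitResult:
    return StayModel.from_tables(adjustments, profiles, **kwargs).fit()


def fit_copy_glmm(adjustments, profiles, **kwargs) -> MixedFitResult:
    return CopyModel.from_tables(adjustments, profiles, **kwargs).fit()


def fit_adjustment_lmm(summaries, profiles, **kwargs) -> MixedFitResult:
    return AdjustmentModel.from_tables(summaries, profiles, **kwargs).fit()


# ---------------------------------------------------------------------------
# Accuracy model
# ---------------------------------------------------------------------------

class AccuracyModel:
    """Linear mixed model of estimate deviations on period (first/second).

    Random structure: school intercept, participant within school, period
    within participant. A negative period coefficient means second
    estimates sit closer to the true count than first estimates.
    """

    def __init__(self, data: pd.DataFrame, include_school: bool = True):
        required = {"deviation", "period", "participant_id", "school"}
        missing = required - set(data.columns)
        if missing:
            raise InvalidArgumentError(f"model frame lacks columns {sorted(missing)}")
        self.data = data.reset_index(drop=True)
        self.include_school = include_school

    @classmethod
    def from_tables(cls, deviations: pd.DataFrame, **kwargs) -> "AccuracyModel":
        return cls(deviations, **kwargs)

    def fit(self, reml: bool = True) -> MixedFitResult:
        df = self.data.copy()
        df["period_code"] = df["period"].map({"first": 0, "second": 1}).astype(float)
        single = df["participant_id"].nunique() < 2
        caught: list[str] = []
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            if self.include_school and not single:
                md = sm.MixedLM.from_formula(
                    "deviation ~ period_code",
                    groups="school",
                    re_formula="1",
                    vc_formula={
                        "participant": "0 + C(participant_id)",
                        "period(participant)": "0 + C(participant_id):C(period)",
                    },
                    data=df,
                )
            else:
                md = sm.MixedLM.from_formula(
                    "deviation ~ period_code",
                    groups="participant_id",
                    re_formula="1",
                    vc_formula={"period(participant)": "0 + C(period)"},
                    data=df,
                )
            try:
                res = md.fit(reml=reml, method="lbfgs", maxiter=500)
            except Exception:
                res = md.fit(reml=reml, method="powell", maxiter=1000)
            caught = sorted({str(w.message) for w in wlist})
        fe = res.fe_params
        se = res.bse[fe.index]
        z = fe / se
        p = 2 * st.norm.sf(np.abs(z))
        table = pd.DataFrame({"estimate": fe, "se": se, "z": z, "p": p}).rename(
            index={"Intercept": "intercept", "period_code": "period"}
        )
        variances = {"residual": float(res.scale)}
        vcomp = np.asarray(res.vcomp).ravel()
        if self.include_school and not single:
            variances["school"] = float(np.asarray(res.cov_re)[0, 0])
            for nm, v in zip(["participant(school)", "period(participant)"], vcomp):
                variances[nm] = float(v)
        else:
            variances["participant"] = float(np.asarray(res.cov_re)[0, 0])
            if vcomp.size:
                variances["period(participant)"] = float(vcomp[0])
        notes = list(caught)
        if single:
            notes.append("single participant: school/participant variances inestimable")
        return MixedFitResult(
            model_name="accuracy (LMM on deviations)",
            params=table,
            n_observations=len(df),
            n_participants=df["participant_id"].nunique(),
            random_effect_variances=variances,
            converged=bool(getattr(res, "converged", True)) and not single,
            method="MixedLM " + ("REML" if reml else "ML") + ", Wald z",
            warnings=notes,
        )


def fit_accuracy_lmm(deviations: pd.DataFrame, **kwargs) -> MixedFitResult:
    return AccuracyModel.from_tables(deviations, **kwargs).fit()


# ---------------------------------------------------------------------------
# Recovery harness
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Replicate-level recovery and calibration summaries."""

    n_replicates: int
    alpha: float
    expected_S_peer: float
    expected_S_adult: float
    mean_S_peer: np.ndarray
    mean_S_adult: np.ndarray
    contrarian_rate: np.ndarray
    overshoot_rate: np.ndarray
    p_model_type: np.ndarray | None = None
    p_interaction: np.ndarray | None = None

    @property
    def bias_S_peer(self) -> float:
        return float(np.mean(self.mean_S_peer) - self.expected_S_peer)

    @property
    def bias_S_adult(self) -> float:
        return float(np.mean(self.mean_S_adult) - self.expected_S_adult)

    @property
    def rmse_S_peer(self) -> float:
        return float(np.sqrt(np.mean((self.mean_S_peer - self.expected_S_peer) ** 2)))

    @property
    def rmse_S_adult(self) -> float:
        return float(np.sqrt(np.mean((self.mean_S_adult - self.expected_S_adult) ** 2)))

    @property
    def rejection_rate_model_type(self) -> float | None:
        if self.p_model_type is None:
            return None
        return float(np.mean(self.p_model_type < self.alpha))

    @property
    def rejection_rate_interaction(self) -> float | None:
        if self.p_interaction is None:
            return None
        return float(np.mean(self.p_interaction < self.alpha))

    def summary(self) -> str:
        lines = [
            f"Recovery harness: {self.n_replicates} replicates, alpha = {self.alpha}",
            f"  S_peer : recovered {np.mean(self.mean_S_peer):.4f} "
            f"(expected {self.expected_S_peer:.4f}, bias {self.bias_S_peer:+.4f}, "
            f"rmse {self.rmse_S_peer:.4f})",
            f"  S_adult: recovered {np.mean(self.mean_S_adult):.4f} "
            f"(expected {self.expected_S_adult:.4f}, bias {self.bias_S_adult:+.4f}, "
            f"rmse {self.rmse_S_adult:.4f})",
            f"  contrarian rate: {np.mean(self.contrarian_rate):.4f}; "
            f"overshoot rate: {np.mean(self.overshoot_rate):.4f}",
        ]
        if self.p_model_type is not None:
            lines.append(
                f"  model_type rejection rate : {self.rejection_rate_model_type:.3f}"
            )
            lines.append(
                f"  interaction rejection rate: {self.rejection_rate_interaction:.3f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "n_replicates": self.n_replicates,
            "alpha": self.alpha,
            "expected_S_peer": self.expected_S_peer,
            "expected_S_adult": self.expected_S_adult,
            "mean_S_peer": float(np.mean(self.mean_S_peer)),
            "mean_S_adult": float(np.mean(self.mean_S_adult)),
            "bias_S_peer": self.bias_S_peer,
            "bias_S_adult": self.bias_S_adult,
            "rmse_S_peer": self.rmse_S_peer,
            "rmse_S_adult": self.rmse_S_adult,
            "contrarian_rate": float(np.mean(self.contrarian_rate)),
            "overshoot_rate": float(np.mean(self.overshoot_rate)),
        }
        if self.p_model_type is not None:
            d["rejection_rate_model_type"] = self.rejection_rate_model_type
            d["rejection_rate_interaction"] = self.rejection_rate_interaction
        return d


def expected_cohort_adjustment(config: CohortConfig, condition: str) -> float:
    """Analytic expectation of the cohort mean S under the omit filter,
    weighting the household mix as configured."""
    params = config.agent_params
    counts = dict(config.household_counts)
    total = sum(counts.values())
    return sum(
        counts[h] / total * params.expected_adjustment(condition, household=h)
        for h in counts
    )


def recovery_harness(
    config: CohortConfig,
    n_replicates: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
    deltas: DeltaSchedule | None = None,
    policy: str = "omit",
    fit_adjustment: bool = False,
    include_school: bool = True,
    bank_members: tuple[int, int] = (24, 14),
    bank_iterations: int = 6,
) -> RecoveryReport:
    """Simulate replicate experiments and measure recovery and calibration.

    Each replicate runs the full pipeline (schedule -> bank -> cohort ->
    sessions -> metrics) from its own child seed and records the cohort
    means of S_peer and S_adult and the realised contrarian/overshoot
    rates. With ``fit_adjustment=True`` the adjustment LMM is fitted per
    replicate and the model_type and interaction p-values are collected:
    the rejection rate of model_type measures power for the configured
    condition effect, and the interaction rejection rate under
    ``household_shift = 0`` measures type-I error against ``alpha``.
    """
    if n_replicates < 1:
        raise InvalidArgumentError("n_replicates must be >= 1")
    deltas = deltas or DeltaSchedule()
    mean_peer, mean_adult = [], []
    contrarian, overshoot = [], []
    p_mt, p_ix = [], []
    for rep in range(n_replicates):
        rep_seed = child_seed(seed, "harness", rep)
        schedule = make_stimulus_schedule(child_seed(rep_seed, "schedule"))
        bank = build_bank(
            schedule,
            n_adults=bank_members[0],
            n_students=bank_members[1],
            n_iterations=bank_iterations,
            estimation_params=config.agent_params,
            seed=child_seed(rep_seed, "bank"),
        )
        profiles = sample_cohort(config, child_seed(rep_seed, "cohort"))
        trials = simulate_experiment(
            config, bank, deltas, seed=rep_seed, schedule=schedule, profiles=profiles
        )
        adjustments = filter_valid(compute_adjustments(trials), policy)
        summaries = participant_summary(adjustments)
        mean_peer.append(summaries["S_peer"].mean())
        mean_adult.append(summaries["S_adult"].mean())
        freqs = heuristic_frequencies(adjustments, pooling="all_rounds")
        contrarian.append(freqs["contrarian"])
        overshoot.append(freqs["overshoot"])
        if fit_adjustment:
            fit = AdjustmentModel.from_tables(
                summaries, profiles, include_school=include_school
            ).fit()
            p_mt.append(fit.pvalue("model_type"))
            p_ix.append(fit.pvalue("model_type:household_type"))
    return RecoveryReport(
        n_replicates=n_replicates,
        alpha=alpha,
        expected_S_peer=expected_cohort_adjustment(config, "peer"),
        expected_S_adult=expected_cohort_adjustment(config, "adult"),
        mean_S_peer=np.asarray(mean_peer),
        mean_S_adult=np.asarray(mean_adult),
        contrarian_rate=np.asarray(contrarian),
        overshoot_rate=np.asarray(overshoot),
        p_model_type=np.asarray(p_mt) if fit_adjustment else None,
        p_interaction=np.asarray(p_ix) if fit_adjustment else None,
    )
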