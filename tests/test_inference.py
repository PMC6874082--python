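"""Paired test, mixed models and recovery harness."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import beastsim as bs
from beastsim.errors import InsufficientDataError


def _summaries(peer, adult):
    peer = list(peer)
    adult = list(adult)
    return pd.DataFrame(
        {
            "participant_id": [f"P{i}" for i in range(len(peer))],
            "S_peer": peer,
            "S_adult": adult,
            "n_valid_peer": [5 if not pd.isna(v) else 0 for v in peer],
            "n_valid_adult": [5 if not pd.isna(v) else 0 for v in adult],
        }
    )


class TestPairedTest:
    def test_hand_computed_example(self):
        # differences (0.1, 0.0, 0.2): mean 0.1, sd 0.1 -> t = sqrt(3), d = 1
        res = bs.paired_test(_summaries([0.3, 0.4, 0.3], [0.4, 0.4, 0.5]))
        assert res.t_statistic == pytest.approx(math.sqrt(3), abs=1e-6)
        assert res.degrees_of_freedom == 2
        assert res.cohens_d == pytest.approx(1.0)
        assert res.mean_peer == pytest.approx(1 / 3)

    def test_agrees_with_first_principles_on_random_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(3, 11))
            peer = rng.uniform(0, 1, n)
            adult = rng.uniform(0, 1, n)
            res = bs.paired_test(_summaries(peer, adult))
            diff = adult - peer
            mean, sd = diff.mean(), diff.std(ddof=1)
            t_oracle = mean / (sd / math.sqrt(n))
            from scipy.stats import t as tdist

            p_oracle = 2 * tdist.sf(abs(t_oracle), n - 1)
            assert res.t_statistic == pytest.approx(t_oracle, rel=1e-10)
            assert res.p_value == pytest.approx(p_oracle, rel=1e-10)
            assert res.cohens_d == pytest.approx(mean / sd, rel=1e-10)

    def test_degenerate_zero_variance(self):
        res = bs.paired_test(_summaries([0.4, 0.5, 0.6], [0.4, 0.5, 0.6]))
        assert res.degenerate
        assert res.t_statistic == 0.0 and res.cohens_d == 0.0

    def test_incomplete_pairs_excluded(self):
        res = bs.paired_test(
            _summaries([0.3, 0.4, 0.3, 0.2], [0.4, 0.4, 0.5, np.nan])
        )
        assert res.n_pairs == 3
        assert res.degrees_of_freedom == 2

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            bs.paired_test(_summaries([0.3], [0.4]))


class TestAdjustmentModel:
    def test_ols_reduction_matches_normal_equations(self):
        rng = np.random.default_rng(11)
        n = 24
        data = pd.DataFrame(
            {
                "participant_id": [f"P{i // 2}" for i in range(n)],
                "school": ["school_1"] * n,
                "S": rng.uniform(0, 1, n),
                "model_type": [i % 2 for i in range(n)],
                "household_type": rng.integers(0, 2, n),
                "gender": rng.integers(0, 2, n),
                "age": rng.integers(-2, 3, n).astype(float),
            }
        )
        fit = bs.AdjustmentModel(data, random_effects=False).fit()
        X = np.column_stack(
            [
                np.ones(n),
                data["model_type"],
                data["household_type"],
                data["model_type"] * data["household_type"],
                data["gender"],
                data["age"],
            ]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ data["S"].to_numpy())
        terms = ["intercept", "model_type", "household_type",
                 "model_type:household_type", "gender", "age"]
        for term, b in zip(terms, beta):
            assert fit.coef(term) == pytest.approx(b, abs=1e-8)

    def test_constant_outcome_gives_flat_model(self):
        data = pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(10) for _ in (0, 1)],
                "school": ["school_1", "school_2"] * 10,
                "S": 0.4,
                "model_type": [0, 1] * 10,
                "household_type": ([0] * 10 + [1] * 10),
                "gender": ([0, 1] * 10),
                "age": 0.0,
            }
        )
        fit = bs.AdjustmentModel(data, random_effects=False).fit()
        assert fit.coef("intercept") == pytest.approx(0.4, abs=1e-10)
        for term in ("model_type", "household_type", "gender"):
            assert fit.coef(term) == pytest.approx(0.0, abs=1e-10)

    def test_row_count_matches_defined_condition_means(self, small_summaries,
                                                       small_profiles):
        model = bs.AdjustmentModel.from_tables(small_summaries, small_profiles)
        defined = small_summaries[["S_peer", "S_adult"]].notna().sum().sum()
        n_analysable_defined = len(model.data)
        assert n_analysable_defined <= defined
        assert n_analysable_defined <= 2 * len(small_profiles)

    def test_recovers_condition_effect_with_strong_shift(self, small_bank):
        params = bs.AgentParams(adult_shift=0.2)
        cfg = replace(bs.CohortConfig().scaled(120), agent_params=params)
        profiles = bs.sample_cohort(cfg, seed=31)
        trials = bs.simulate_experiment(cfg, small_bank, seed=32, profiles=profiles)
        adj = bs.filter_valid(bs.compute_adjustments(trials), "omit")
        summaries = bs.participant_summary(adj)
        fit = bs.AdjustmentModel.from_tables(summaries, profiles).fit()
        assert fit.coef("model_type") > 0
        assert fit.pvalue("model_type") < 0.01
        # no household effect was generated
        assert fit.pvalue("model_type:household_type") > 0.01


@pytest.fixture(scope="module")
def strong_contrast(small_bank):
    params = bs.AgentParams(
        peer_weights=bs.MixtureWeights(0.45, 0.10, 0.02, 0.05),
        adult_weights=bs.MixtureWeights(0.15, 0.40, 0.02, 0.05),
    )
    cfg = replace(bs.CohortConfig().scaled(96), agent_params=params)
    profiles = bs.sample_cohort(cfg, seed=9)
    trials = bs.simulate_experiment(cfg, small_bank, seed=17, profiles=profiles)
    adj = bs.filter_valid(bs.compute_adjustments(trials), "omit")
    return adj, profiles


class TestBinaryHeuristicModels:
    def test_stay_model_negative_condition_effect(self, strong_contrast):
        adj, profiles = strong_contrast
        fit = bs.fit_stay_glmm(adj, profiles)
        assert fit.converged
        assert fit.coef("model_type") < 0
        assert fit.pvalue("model_type") < 0.01

    def test_copy_model_positive_condition_effect(self, strong_contrast):
        adj, profiles = strong_contrast
        fit = bs.fit_copy_glmm(adj, profiles)
        assert fit.converged
        assert fit.coef("model_type") > 0
        assert fit.pvalue("model_type") < 0.01

    def test_constant_outcome_flagged(self, small_adjustments, small_profiles):
        never_stay = small_adjustments[small_adjustments["s"] != 0]
        fit = bs.fit_stay_glmm(never_stay, small_profiles)
        assert not fit.converged
        assert fit.params["estimate"].isna().all()


class TestAccuracyModel:
    def test_period_effect_negative_when_social_info_helps(self, small_trials):
        fit = bs.fit_accuracy_lmm(bs.deviation_table(small_trials))
        assert fit.coef("period") < 0
        assert fit.pvalue("period") < 0.01

    def test_zero_period_effect_when_E2_equals_E1(self, small_trials):
        frozen = small_trials.copy()
        frozen["E2"] = frozen["E1"]
        # X==E2 would be fine; metrics are not involved here
        fit = bs.fit_accuracy_lmm(bs.deviation_table(frozen))
        assert fit.coef("period") == pytest.approx(0.0, abs=1e-6)

    def test_single_participant_flagged(self, small_trials):
        one = small_trials[small_trials["participant_id"] ==
                           small_trials["participant_id"].iloc[0]]
        fit = bs.fit_accuracy_lmm(bs.deviation_table(one))
        assert not fit.converged
        assert any("single participant" in w for w in fit.warnings)


class TestRecoveryHarness:
    def test_report_structure_and_consistency(self):
        cfg = bs.CohortConfig().scaled(32)
        report = bs.recovery_harness(cfg, n_replicates=3, seed=2,
                                     fit_adjustment=True)
        assert report.n_replicates == 3
        assert report.mean_S_peer.shape == (3,)
        assert np.isfinite(report.mean_S_adult).all()
        assert report.p_interaction.shape == (3,)
        assert ((report.p_interaction >= 0) & (report.p_interaction <= 1)).all()
        assert 0 <= report.rejection_rate_interaction <= 1
        d = report.to_dict()
        assert "rmse_S_adult" in d and "overshoot_rate" in d

    def test_expected_values_use_household_mix(self):
        cfg = replace(
            bs.CohortConfig(),
            agent_params=bs.AgentParams(household_shift=0.1),
        )
        mixed = bs.expected_cohort_adjustment(cfg, "peer")
        nuclear_only = cfg.agent_params.expected_adjustment("peer", "nuclear")
        extended_only = cfg.agent_params.expected_adjustment("peer", "extended")
        assert nuclear_only < mixed < extended_only
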