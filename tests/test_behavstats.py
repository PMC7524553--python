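"""Behavioural statistics: psychometric/logistic fits, parameter
recovery against the synthetic agent, PVB index, bootstrap and CV."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from provar import behavstats as bs
from provar import trialgen as tg


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestPsychometric:
    def test_curve_is_half_at_zero_for_any_parameters(self):
        for alpha, beta in [(1, 1), (10, 1.5), (3, 0.7)]:
            assert bs.psychometric_curve(0.0, alpha, beta) == pytest.approx(0.5)

    def test_lapse_bounds_asymptotes(self):
        x = np.array([-1e3, 1e3])
        p = bs.hsd_curve(x, alpha=10, beta=1.5, delta=0.0, y0=0.1)
        assert p[1] == pytest.approx(0.9, abs=1e-6)
        assert p[0] == pytest.approx(0.1, abs=1e-6)

    def test_parameter_recovery(self):
        # choices drawn from a known psychometric curve; oracle = generator
        rng = _rng(1)
        alpha, beta = 10.0, 1.5
        ts = tg.generate_trialset(20_000, seed=31, config=tg.GenConfig(round_heights=False))
        summ = bs.evidence_summary(ts)
        x = np.abs(summ["dmean"].to_numpy())
        p = bs.psychometric_curve(x, alpha, beta)
        correct = rng.random(len(x)) < p
        # correctness-coded responses; chose_left chosen consistently
        chose_left = np.where(summ["dmean"] > 0, correct, ~correct)
        cs = tg.ChoiceSet(ts, chose_left, correct)
        fit = bs.fit_psychometric(cs, "accuracy")
        assert fit.alpha == pytest.approx(alpha, rel=0.05)
        assert fit.beta_order == pytest.approx(beta, rel=0.05)

    def test_too_few_trials_rejected(self):
        ts = tg.generate_trialset(10, seed=1)
        cs = tg.simulate_logistic_agent(ts, tg.AgentSpec(), _rng(0))
        with pytest.raises(ValueError):
            bs.fit_psychometric(cs)


class TestLocalWins:
    def test_worked_example(self):
        left = np.array([50, 55, 56, 48, 80, 45, 30, 50.0])
        right = np.array([55, 48, 90, 34, 70, 50, 50, 70.0])
        t = tg.Trial(
            tg.StimulusStream(left, tg.GenerativeParams(50, 12, "narrow")),
            tg.StimulusStream(right, tg.GenerativeParams(50, 12, "narrow")),
            "ChooseTall",
            "Regular",
        )
        assert bs.local_wins(t) == (3, 5)

    def test_identical_streams_all_ties(self):
        h = np.array([50.0, 60.0, 40.0, 55.0])
        t = tg.Trial(
            tg.StimulusStream(h, tg.GenerativeParams(50, 12, "narrow")),
            tg.StimulusStream(h.copy(), tg.GenerativeParams(50, 12, "narrow")),
            "ChooseTall",
            "Regular",
        )
        assert bs.local_wins(t) == (0, 0)

    def test_dominance(self):
        t = tg.Trial(
            tg.StimulusStream(np.full(8, 80.0), tg.GenerativeParams(80, 12, "narrow")),
            tg.StimulusStream(np.full(8, 20.0), tg.GenerativeParams(20, 12, "narrow")),
            "ChooseTall",
            "Regular",
        )
        assert bs.local_wins(t) == (8, 0)


class TestDesigns:
    def test_pvb_columns_are_differences(self):
        left = np.array([70, 50, 60, 60.0])
        right = np.array([55, 45, 50, 50.0])
        t = tg.Trial(
            tg.StimulusStream(left, tg.GenerativeParams(60, 12, "narrow")),
            tg.StimulusStream(right, tg.GenerativeParams(50, 12, "narrow")),
            "ChooseTall",
            "Regular",
        )
        cs = tg.ChoiceSet(tg.TrialSet([t], {}, 0), [True], [True])
        X, y = bs.build_design(cs, bs.DesignSpec("pvb"))
        assert X["dmean"].iloc[0] == pytest.approx(left.mean() - right.mean())
        assert X["dsd"].iloc[0] == pytest.approx(
            np.std(left, ddof=1) - np.std(right, ddof=1)
        )

    def test_full_model_has_twelve_regressors_plus_intercept(self, regular_trials_2k):
        cs = tg.simulate_logistic_agent(regular_trials_2k, tg.AgentSpec(), _rng(2))
        X, _ = bs.build_design(cs, bs.DesignSpec("full"))
        assert X.shape[1] == 13
        Xn, _ = bs.build_design(cs, bs.DesignSpec("full_no_sd"))
        assert Xn.shape[1] == 11
        assert set(X.columns) - set(Xn.columns) == {"sd_l", "sd_r"}

    def test_temporal_design_one_column_per_sample(self, regular_trials_2k):
        cs = tg.simulate_logistic_agent(regular_trials_2k, tg.AgentSpec(), _rng(3))
        X, _ = bs.build_design(cs, bs.DesignSpec("temporal"))
        assert [c for c in X.columns if c != "intercept"] == [f"w{k}" for k in range(1, 9)]


class TestGlmFits:
    def test_recovers_generating_coefficients(self, agent_choices_20k):
        ts, agent, cs = agent_choices_20k
        res = bs.fit_pvb(cs)
        for name, truth in [("dmean", agent.beta_mean), ("dsd", agent.beta_sd)]:
            est, se = res.coefficients[name], res.standard_errors[name]
            assert abs(est - truth) < 2.5 * se

    def test_intercept_not_significant_for_symmetric_agent(self, agent_choices_20k):
        _, _, cs = agent_choices_20k
        res = bs.fit_pvb(cs)
        assert abs(res.t_stats["intercept"]) < 3.0

    def test_duplicating_trials_scales_t_by_sqrt2(self, agent_choices_20k):
        # GLM theory: coefficients unchanged, SEs shrink by sqrt(2)
        _, _, cs = agent_choices_20k
        res1 = bs.fit_pvb(cs)
        doubled = tg.ChoiceSet(
            tg.TrialSet(list(cs.trials) * 2, {}, 0),
            np.concatenate([cs.chose_left] * 2),
            np.concatenate([cs.correct] * 2),
        )
        res2 = bs.fit_pvb(doubled)
        assert res2.coefficients["dmean"] == pytest.approx(res1.coefficients["dmean"], rel=1e-6)
        ratio = res2.t_stats["dmean"] / res1.t_stats["dmean"]
        assert ratio == pytest.approx(np.sqrt(2), rel=1e-3)

    def test_separation_raises_named_error(self):
        ts = tg.generate_trialset(200, seed=33)
        summ = bs.evidence_summary(ts)
        chose_left = (summ["dmean"] > 0).to_numpy()  # deterministic chooser
        cs = tg.ChoiceSet(ts, chose_left, np.ones(len(ts), bool))
        X, y = bs.build_design(cs, bs.DesignSpec("pvb"))
        with pytest.raises(bs.SeparationError):
            bs.fit_choice_glm(X, y)

    def test_pvb_ratio_recovered_within_five_percent_at_50k(self):
        ts = tg.generate_trialset(
            50_000, seed=55, config=tg.GenConfig(round_heights=False)
        )
        agent = tg.AgentSpec(beta_mean=0.10, beta_sd=0.05)  # generating ratio 0.5
        cs = tg.simulate_logistic_agent(ts, agent, _rng(56))
        res = bs.fit_pvb(cs)
        assert bs.pvb_index(res) == pytest.approx(0.5, rel=0.05)

    def test_left_right_relabeling_flips_signs_only(self, agent_choices_20k):
        ts, _, cs = agent_choices_20k
        res = bs.fit_pvb(cs)
        swapped_trials = [
            tg.Trial(t.right, t.left, t.context, t.condition) for t in ts
        ]
        cs2 = tg.ChoiceSet(
            tg.TrialSet(swapped_trials, {}, 0), ~cs.chose_left, cs.correct
        )
        res2 = bs.fit_pvb(cs2)
        assert res2.coefficients["dmean"] == pytest.approx(
            res.coefficients["dmean"], rel=1e-6
        )
        assert res2.coefficients["intercept"] == pytest.approx(
            -res.coefficients["intercept"], rel=1e-6
        )
        assert bs.pvb_index(res2) == pytest.approx(bs.pvb_index(res), rel=1e-6)


class TestLapseMle:
    def test_recovers_lapse_rate(self):
        config = tg.GenConfig(round_heights=False)
        ts = tg.generate_trialset(20_000, config=config, seed=8)
        agent = tg.AgentSpec(beta_mean=0.10, beta_sd=0.02, lapse=0.12)
        cs = tg.simulate_logistic_agent(ts, agent, _rng(9))
        X, y = bs.build_design(cs, bs.DesignSpec("pvb", include_lapse=True))
        res = bs.fit_lapse_mle(X, y, rng=_rng(10), n_restarts=4)
        # Y0 trades off against the slope along a flat likelihood ridge
        # (evidence saturates near |logit| ~ 2), so point recovery is
        # CI-scale, not SE-scale
        assert res.y0 == pytest.approx(0.12, abs=0.07)
        assert res.coefficients["dmean"] == pytest.approx(0.10, abs=0.03)

    def test_nested_in_plain_glm_when_no_lapses(self, agent_choices_20k):
        _, agent, cs = agent_choices_20k
        X, y = bs.build_design(cs, bs.DesignSpec("pvb"))
        glm = bs.fit_choice_glm(X, y)
        res = bs.fit_lapse_mle(X, y, rng=_rng(11), n_restarts=3)
        assert res.y0 < 0.02
        assert res.coefficients["dmean"] == pytest.approx(
            glm.coefficients["dmean"], rel=0.05
        )

    def test_huge_penalty_shrinks_everything(self, agent_choices_20k):
        # the penalised optimum balances an O(n) likelihood gradient
        # against 2*lambda*beta, so "toward zero" means strong relative
        # shrinkage, not exactly zero
        _, _, cs = agent_choices_20k
        X, y = bs.build_design(cs, bs.DesignSpec("pvb"))
        free = bs.fit_lapse_mle(X, y, l2_lambda=0.01, rng=_rng(12), n_restarts=2)
        res = bs.fit_lapse_mle(X, y, l2_lambda=1e6, rng=_rng(12), n_restarts=2)
        assert abs(res.coefficients["dmean"]) < 0.25 * abs(free.coefficients["dmean"])
        assert res.y0 < 0.01


class TestPvbIndex:
    def test_simple_ratio_and_scale_invariance(self):
        def make(bm, bsd):
            return bs.RegressionResult(
                {"intercept": 0.0, "dmean": bm, "dsd": bsd}, {}, {}, 0.0, 100, "glm"
            )

        assert bs.pvb_index(make(1.0, 0.2)) == pytest.approx(0.2)
        assert bs.pvb_index(make(0.5, 0.1)) == pytest.approx(0.2)
        assert bs.pvb_index(make(1.0, 1.0)) == pytest.approx(1.0)

    def test_nonpositive_mean_coefficient_flagged(self):
        res = bs.RegressionResult(
            {"intercept": 0.0, "dmean": -0.1, "dsd": 0.2}, {}, {}, 0.0, 100, "glm"
        )
        with pytest.raises(ValueError, match="undefined"):
            bs.pvb_index(res)


class TestBootstrap:
    def test_choice_rate_se_matches_binomial(self, regular_trials_2k):
        cs = tg.simulate_logistic_agent(regular_trials_2k, tg.AgentSpec(), _rng(14))
        boot = bs.bootstrap_se(
            lambda d: {"rate": float(np.mean(d.chose_left))}, cs, B=400, rng=_rng(15)
        )
        p = np.mean(cs.chose_left)
        expected = np.sqrt(p * (1 - p) / len(cs))
        assert boot["rate"]["se"] == pytest.approx(expected, rel=0.15)

    def test_degenerate_response_gives_zero_se(self, regular_trials_2k):
        cs = tg.ChoiceSet(
            regular_trials_2k,
            np.ones(len(regular_trials_2k), bool),
            np.ones(len(regular_trials_2k), bool),
        )
        boot = bs.bootstrap_se(
            lambda d: {"rate": float(np.mean(d.chose_left))}, cs, B=150, rng=_rng(16)
        )
        assert boot["rate"]["se"] == 0.0

    def test_same_seed_identical_cis(self, regular_trials_2k):
        cs = tg.simulate_logistic_agent(regular_trials_2k, tg.AgentSpec(), _rng(17))
        f = lambda d: {"rate": float(np.mean(d.chose_left))}
        b1 = bs.bootstrap_se(f, cs, B=150, rng=_rng(18))
        b2 = bs.bootstrap_se(f, cs, B=150, rng=_rng(18))
        assert b1["rate"]["ci_low"] == b2["rate"]["ci_low"]
        assert b1["rate"]["ci_high"] == b2["rate"]["ci_high"]


class TestCrossValidation:
    def test_generator_matched_model_wins(self):
        ts = tg.generate_trialset(4000, seed=41, config=tg.GenConfig(round_heights=False))
        agent = tg.AgentSpec(beta_mean=0.10, beta_sd=0.05)
        cs = tg.simulate_logistic_agent(ts, agent, _rng(19))
        out = bs.crossval_loglik(
            cs,
            [bs.DesignSpec("pvb"), bs.DesignSpec("full_no_sd")],
            k=5,
            reps=3,
            rng=_rng(20),
        )
        assert out["pvb"] > out["full_no_sd"]

    def test_coin_flip_agent_at_entropy(self, regular_trials_2k):
        cs = tg.simulate_logistic_agent(
            regular_trials_2k, tg.AgentSpec(beta_mean=0.0, beta_sd=0.0), _rng(21)
        )
        out = bs.crossval_loglik(cs, [bs.DesignSpec("pvb")], k=5, reps=3, rng=_rng(22))
        per_trial = out["pvb"] / len(cs)
        assert per_trial == pytest.approx(np.log(0.5), abs=0.01)
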