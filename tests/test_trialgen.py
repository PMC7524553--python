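"""Stimulus-generator contracts: published constraints, determinism,
evidence mapping and the synthetic logistic agent."""

import numpy as np
import pytest
from scipy.special import expit

from provar import trialgen as tg


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestRegularTrials:
    def test_constraints_hold_for_every_emitted_trial(self):
        config = tg.GenConfig(round_heights=False)
        rng = _rng(1)
        for _ in range(300):
            t = tg.generate_regular_trial(rng, config)
            for s in (t.left, t.right):
                assert s.heights.min() >= 1 and s.heights.max() <= 99
                assert abs(s.sd - s.params.sigma) <= 4
                assert s.params.sigma in (12.0, 24.0)
                # mu = 50 + Z*sigma with Z in [-0.25, 0.25]
                z = (s.params.mu - 50.0) / s.params.sigma
                assert -0.25 <= z <= 0.25

    def test_stream_type_composition(self):
        ts = tg.generate_trialset(3000, seed=3)
        kinds = [(t.left.params.stream_type, t.right.params.stream_type) for t in ts]
        nn = np.mean([k == ("narrow", "narrow") for k in kinds])
        bb = np.mean([k == ("broad", "broad") for k in kinds])
        assert nn == pytest.approx(0.25, abs=0.03)
        assert bb == pytest.approx(0.25, abs=0.03)

    def test_generative_means_symmetric_about_50(self):
        ts = tg.generate_trialset(4000, seed=4)
        mus = [t.left.params.mu for t in ts] + [t.right.params.mu for t in ts]
        assert np.mean(mus) == pytest.approx(50.0, abs=0.3)

    def test_realized_sd_matches_generative_procedure(self):
        # oracle expectations from direct simulation of the printed
        # procedure (sample-SD bias c4(8)=0.965 plus range truncation):
        # narrow 11.66, broad 23.41
        config = tg.GenConfig(round_heights=False)
        rng = _rng(5)
        sds = {"narrow": [], "broad": []}
        while min(len(v) for v in sds.values()) < 4000:
            t = tg.generate_regular_trial(rng, config)
            for s in (t.left, t.right):
                sds[s.params.stream_type].append(s.sd)
        assert np.mean(sds["narrow"]) == pytest.approx(11.66, abs=0.2)
        assert np.mean(sds["broad"]) == pytest.approx(23.41, abs=0.3)

    def test_pharma_mode_enforces_mean_separation_and_six_samples(self):
        config = tg.GenConfig(pharma=True)
        rng = _rng(6)
        for _ in range(100):
            t = tg.generate_regular_trial(rng, config)
            assert t.n_samples == 6
            assert abs(t.left.mean - t.right.mean) > 4.0 - 0.5  # rounding slack

    def test_rounding_produces_integer_heights(self):
        t = tg.generate_regular_trial(_rng(7), tg.GenConfig(round_heights=True))
        assert np.all(t.left.heights == np.rint(t.left.heights))


class TestNarrowBroadTrials:
    @pytest.mark.parametrize("condition", ["NarrowCorrect", "BroadCorrect"])
    def test_mean_difference_window(self, condition):
        config = tg.GenConfig(round_heights=False)
        rng = _rng(8)
        for _ in range(100):
            t = tg.generate_narrow_broad_trial(condition, rng, config)
            narrow = t.left if t.left.params.stream_type == "narrow" else t.right
            broad = t.right if narrow is t.left else t.left
            diff = narrow.mean - broad.mean
            if condition == "BroadCorrect":
                diff = -diff
            assert 2.0 <= diff <= 14.0

    def test_ambiguous_difference_below_four(self):
        config = tg.GenConfig(round_heights=False)
        rng = _rng(9)
        for _ in range(100):
            t = tg.generate_narrow_broad_trial("Ambiguous", rng, config)
            assert abs(t.left.mean - t.right.mean) < 4.0

    def test_side_assignment_balanced(self):
        rng = _rng(10)
        left_narrow = [
            tg.generate_narrow_broad_trial("Ambiguous", rng).left.params.stream_type
            == "narrow"
            for _ in range(600)
        ]
        assert np.mean(left_narrow) == pytest.approx(0.5, abs=0.06)

    def test_pharma_rejects_non_ambiguous(self):
        with pytest.raises(ValueError):
            tg.generate_narrow_broad_trial(
                "NarrowCorrect", _rng(0), tg.GenConfig(pharma=True)
            )


class TestHalfHalfTrials:
    def test_strong_half_exceeds_weak_half(self):
        config = tg.GenConfig(round_heights=False)
        rng = _rng(11)
        for _ in range(60):
            t = tg.generate_half_half_trial(rng, config)
            for s in (t.left, t.right):
                half = t.n_samples // 2
                first, second = s.heights[:half].mean(), s.heights[half:].mean()
                if s.params.stream_type == "tall_first":
                    assert first - second >= 7.5
                else:
                    assert second - first >= 7.5
                assert s.heights.min() >= 1 and s.heights.max() <= 99

    def test_options_share_generative_mean(self):
        rng = _rng(12)
        diffs = []
        for _ in range(400):
            t = tg.generate_half_half_trial(rng, tg.GenConfig(round_heights=False))
            diffs.append(t.left.mean - t.right.mean)
        assert np.mean(diffs) == pytest.approx(0.0, abs=0.5)

    def test_odd_sample_count_rejected(self):
        with pytest.raises(ValueError):
            tg.generate_half_half_trial(_rng(0), tg.GenConfig(n_samples=7))


class TestTrialSet:
    def test_empty_request(self):
        ts = tg.generate_trialset(0, seed=0)
        assert len(ts) == 0

    def test_bit_identical_regeneration(self):
        a = tg.generate_trialset(50, {"Regular": 0.5, "Ambiguous": 0.5}, seed=42)
        b = tg.generate_trialset(50, {"Regular": 0.5, "Ambiguous": 0.5}, seed=42)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.left.heights, tb.left.heights)
            assert np.array_equal(ta.right.heights, tb.right.heights)
            assert ta.context == tb.context and ta.condition == tb.condition

    def test_composition_must_sum_to_one(self):
        with pytest.raises(ValueError):
            tg.generate_trialset(10, {"Regular": 0.6}, seed=0)


class TestEvidenceMapping:
    def test_choose_tall_is_identity_and_choose_short_complements(self):
        h = np.array([70.0, 50.0, 30.0])
        s = tg.StimulusStream(h, tg.GenerativeParams(50, 12, "narrow"))
        tall = tg.Trial(s, s, "ChooseTall", "Regular")
        short = tg.Trial(s, s, "ChooseShort", "Regular")
        assert np.array_equal(tg.evidence_for_context(tall, "left"), [70, 50, 30])
        assert np.array_equal(tg.evidence_for_context(short, "left"), [30, 50, 70])
        # h = 50 is the fixed point of the mapping
        assert tg.evidence_for_context(tall, "left")[1] == 50
        assert tg.evidence_for_context(short, "left")[1] == 50


class TestLogisticAgent:
    def test_fully_lapsed_agent_is_coin_flip(self, regular_trials_2k):
        agent = tg.AgentSpec(beta_mean=5.0, beta_sd=5.0, lapse=0.5)
        p = tg.agent_choice_probability(regular_trials_2k, agent)
        assert np.allclose(p, 0.5)

    def test_symmetric_agent_near_half(self, regular_trials_2k):
        agent = tg.AgentSpec(beta0=0.0, beta_mean=0.0, beta_sd=0.0)
        cs = tg.simulate_logistic_agent(regular_trials_2k, agent, _rng(13))
        assert np.mean(cs.chose_left) == pytest.approx(0.5, abs=0.035)

    def test_choice_frequencies_match_closed_form(self, agent_choices_20k):
        # oracle: direct evaluation of the lapse-logistic formula
        ts, agent, cs = agent_choices_20k
        p = tg.agent_choice_probability(ts, agent)
        bins = np.digitize(p, [0.2, 0.4, 0.6, 0.8])
        for b in range(5):
            sel = bins == b
            if sel.sum() < 200:
                continue
            expected = p[sel].mean()
            se = np.sqrt(expected * (1 - expected) / sel.sum())
            assert np.mean(cs.chose_left[sel]) == pytest.approx(expected, abs=4 * se)

    def test_infeasible_config_raises_attempt_cap(self):
        config = tg.GenConfig(pharma=True, pharma_min_diff=60.0, max_attempts=50)
        with pytest.raises(tg.AttemptCapExceeded):
            tg.generate_regular_trial(_rng(14), config)
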