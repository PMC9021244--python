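"""Strategy models: updates, values, policies, likelihoods."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riskylearn import agent_models as am
from riskylearn.agent_models import (MODELS, BeliefState, ParamSet,
                                     bio_update, choice_prob,
                                     effective_learning_rate, epsilon_prob,
                                     init_belief, log_likelihood,
                                     risky_choice_prob, risky_value,
                                     rl_update, simulate_agent, utility)
from riskylearn.task_engine import make_block_schedule, session_tapes

from conftest import simulate_one


class TestUtility:
    def test_identity_at_unit_exponent(self):
        assert utility(20, 1.0) == 20.0

    def test_sure_payoff_is_reference_point(self):
        assert utility(10, 2.7) == pytest.approx(10.0)
        assert utility(0, 0.3) == 0.0

    def test_convex_exponent_overvalues_win(self):
        assert utility(20, 1.5) == pytest.approx(10 * 2 ** 1.5)
        assert utility(20, 1.5) > 20 > utility(20, 0.5)

    def test_nonpositive_exponent_rejected(self):
        with pytest.raises(ValueError):
            utility(20, 0.0)


class TestRlUpdate:
    def test_delta_rule(self):
        spec, p = MODELS["m1a"], ParamSet(alpha=0.5, beta=1, q1=10)
        assert rl_update(BeliefState(q=10), 20, p, spec).q == 15.0
        assert rl_update(BeliefState(q=10), 0,
                         ParamSet(alpha=0.0, beta=1, q1=10), spec).q == 10.0

    def test_negative_rate_moves_value_away_from_outcome(self):
        spec = MODELS["gf_rl"]
        p = ParamSet(alpha=-0.5, kappa=1.0, beta=1, q1=10)
        assert rl_update(BeliefState(q=10), 20, p, spec).q == 5.0

    def test_sure_outcome_rejected(self):
        with pytest.raises(ValueError):
            rl_update(BeliefState(q=10), 10,
                      ParamSet(alpha=0.5, beta=1, q1=10), MODELS["m1a"])

    @given(q=st.floats(0, 20), alpha=st.floats(0.001, 0.999),
           won=st.booleans())
    @settings(max_examples=50, deadline=None)
    def test_value_stays_in_payoff_range(self, q, alpha, won):
        spec = MODELS["m1a"]
        p = ParamSet(alpha=alpha, beta=1, q1=q)
        new = rl_update(BeliefState(q=q), 20 if won else 0, p, spec)
        assert 0.0 <= new.q <= 20.0


class TestBioUpdate:
    def test_pseudo_count_increments(self):
        spec = MODELS["m2a"]
        p = ParamSet(pi=1.0, beta=1, a1=1.0)
        s = bio_update(BeliefState(a=1, b=1), 20, p, spec)
        assert (s.a, s.b) == (2.0, 1.0)
        p = ParamSet(pi=0.5, beta=1, a1=1.0)
        s = bio_update(BeliefState(a=1, b=1), 0, p, spec)
        assert (s.a, s.b) == (1.0, 1.5)

    def test_negative_rate_clips_at_floor_and_lowers_mean(self):
        spec = MODELS["gf_bio"]
        p = ParamSet(pi_pos=-1.0, pi_neg=-1.0, beta=1, a1=0.5)
        before = BeliefState(a=0.5, b=1.0)
        after = bio_update(before, 20, p, spec)
        assert after.a == pytest.approx(0.001)
        assert (after.a / (after.a + after.b)
                < before.a / (before.a + before.b))

    def test_sure_outcome_rejected(self):
        with pytest.raises(ValueError):
            bio_update(BeliefState(a=1, b=1), 10,
                       ParamSet(pi=1.0, beta=1, a1=1.0), MODELS["m2a"])


class TestRiskyValue:
    def test_posterior_mean_times_payoff(self):
        v = risky_value(BeliefState(a=2, b=1),
                        ParamSet(pi=1, beta=1, a1=1), MODELS["m2a"])
        assert v == pytest.approx(20 * 2 / 3)

    def test_uncertainty_bonus(self):
        spec = MODELS["m2d"]
        state = BeliefState(a=1, b=1)
        assert risky_value(state, ParamSet(pi=1, phi=0.0, beta=1, a1=1),
                           spec) == pytest.approx(10.0)
        v = risky_value(state, ParamSet(pi=1, phi=1.0, beta=1, a1=1), spec)
        assert v == pytest.approx(10 + 20 * math.sqrt(1 / 12))

    @given(a=st.floats(0.01, 50), b=st.floats(0.01, 50))
    @settings(max_examples=50, deadline=None)
    def test_bio_mean_is_proper_probability(self, a, b):
        v = risky_value(BeliefState(a=a, b=b),
                        ParamSet(pi=1, beta=1, a1=1), MODELS["m2a"])
        assert 0.0 < v < 20.0


class TestEffectiveLearningRate:
    @given(a=st.floats(0.1, 20), b=st.floats(0.1, 20),
           pi=st.floats(0.01, 5), won=st.booleans())
    @settings(max_examples=80, deadline=None)
    def test_matches_posterior_mean_movement(self, a, b, pi, won):
        state = BeliefState(a=a, b=b)
        rate = effective_learning_rate(state, pi)
        mu = a / (a + b)
        obs = 1.0 if won else 0.0
        mu_new = ((a + pi) / (a + b + pi)) if won else (a / (a + b + pi))
        assert mu_new == pytest.approx(mu + rate * (obs - mu), abs=1e-12)

    def test_decays_with_evidence_and_vanishes_at_zero(self):
        assert effective_learning_rate(BeliefState(a=1, b=1), 1.0) \
            == pytest.approx(1 / 3)
        assert effective_learning_rate(BeliefState(a=500, b=500), 1.0) < 0.01
        assert effective_learning_rate(BeliefState(a=1, b=1), 0.0) == 0.0


class TestChoicePolicy:
    def test_zero_inverse_temperature_is_indifference(self):
        assert choice_prob(19.0, 10.0, 0.0) == 0.5
        assert choice_prob(14.0, 14.0, 3.0) == 0.5

    def test_logistic_at_known_difference(self):
        assert choice_prob(14.0, 10.0, 1.0) \
            == pytest.approx(1 / (1 + math.exp(-4)))

    @given(v1=st.floats(-10, 30), v2=st.floats(-10, 30),
           beta=st.floats(0.01, 10))
    @settings(max_examples=60, deadline=None)
    def test_strictly_increasing_in_risky_value(self, v1, v2, beta):
        lo, hi = sorted((v1, v2))
        if beta * (hi - lo) < 1e-6:  # below float resolution of the logistic
            return
        p_lo, p_hi = choice_prob(lo, 10.0, beta), choice_prob(hi, 10.0, beta)
        if p_lo < 1e-12 or p_hi > 1 - 1e-12:  # saturated tails
            assert p_lo <= p_hi
        else:
            assert p_lo < p_hi

    def test_epsilon_policy_is_stateless(self):
        p = ParamSet(epsilon=0.9)
        assert epsilon_prob(p) == 0.9
        rng = np.random.default_rng(0)
        draws = rng.random(10000) < epsilon_prob(p)
        assert abs(draws.mean() - 0.9) < 0.01
        with pytest.raises(ValueError):
            epsilon_prob(ParamSet(epsilon=1.0))


class TestConjugateOracle:
    """Model 2B with unit update rates is an exact Bayesian observer."""

    @given(seq=st.lists(st.booleans(), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_posterior_mean_matches_beta_binomial(self, seq):
        spec = MODELS["m2b"]
        params = ParamSet(pi_pos=1.0, pi_neg=1.0, beta=1.0, a1=1.0)
        state = init_belief(spec, params)
        assert (state.a, state.b) == (1.0, 1.0)
        for i, won in enumerate(seq, start=1):
            state = bio_update(state, 20 if won else 0, params, spec)
            wins = sum(seq[:i])
            exact = (wins + 1) / (i + 2)
            assert state.a / (state.a + state.b) \
                == pytest.approx(exact, abs=1e-12)


def _reference_loglik(model, params, df):
    """Independent pure-Python unroll of the choice likelihood.

    Works on the log scale throughout: gambler's-fallacy values grow
    geometrically, so the linear-scale probability can saturate to 1.
    """
    spec = MODELS[model]

    def log_logistic(x):
        return -math.log1p(math.exp(-x)) if x >= 0 \
            else x - math.log1p(math.exp(x))

    total = 0.0
    for _, blk in df.sort_values(["block", "trial"]).groupby("block"):
        state = init_belief(spec, params)
        for _, row in blk.iterrows():
            if spec.family == "EPS":
                lp_risky = math.log(params.epsilon)
                lp_sure = math.log1p(-params.epsilon)
            else:
                x = params.beta * (risky_value(state, params, spec) - 10.0)
                lp_risky = log_logistic(x)
                lp_sure = log_logistic(-x)
            if row["choice"] == "risky":
                total += lp_risky
                state = am.belief_update(state, row["outcome"], params, spec)
            else:
                total += lp_sure
    return total


_CASES = [
    ("m1a", dict(alpha=0.3, beta=2.0, q1=12.0)),
    ("m1b", dict(alpha_pos=0.5, alpha_neg=0.2, beta=1.5, q1=8.0)),
    ("m1c", dict(alpha=0.4, kappa=1.6, beta=0.8, q1=15.0)),
    ("m2a", dict(pi=1.0, beta=2.0, a1=1.0)),
    ("m2b", dict(pi_pos=1.5, pi_neg=0.7, beta=1.0, a1=1.2)),
    ("m2c", dict(pi=0.8, kappa=0.7, beta=3.0, a1=0.8)),
    ("m2d", dict(pi=1.2, phi=-2.0, beta=1.0, a1=1.0)),
    ("gf_rl", dict(alpha=-0.5, kappa=1.2, beta=2.0, q1=10.0)),
    ("gf_bio", dict(pi_pos=-1.0, pi_neg=-0.5, beta=1.5, a1=1.5)),
    ("eps", dict(epsilon=0.35)),
]


class TestLogLikelihood:
    @pytest.mark.parametrize("model,params", _CASES)
    def test_kernel_matches_stepwise_composition(self, model, params):
        """The fitting kernel and the single-step operations are one
        computation: they agree to numerical precision on every model."""
        df = simulate_one("eps", seed=31, epsilon=0.5)
        ll = log_likelihood(MODELS[model], ParamSet(**params), df)
        assert ll == pytest.approx(
            _reference_loglik(model, ParamSet(**params), df), rel=1e-11)
        assert ll < 0.0

    def test_uniform_policy_likelihood(self):
        df = simulate_one("m1c", seed=5, alpha=0.3, kappa=1.3, beta=1.0,
                          q1=12.0)
        ll = log_likelihood(MODELS["m1a"],
                            ParamSet(alpha=0.5, beta=0.0, q1=10.0), df)
        assert ll == pytest.approx(200 * math.log(0.5))
        ll_eps = log_likelihood(MODELS["eps"], ParamSet(epsilon=0.5), df)
        assert ll_eps == pytest.approx(ll)

    def test_hand_unrolled_single_block(self):
        """20 forced risky choices against a known tape, unrolled by hand
        with the delta rule and the logistic policy."""
        import pandas as pd
        wins = [1, 0, 1, 1, 0, 1, 0, 0, 1, 1, 0, 1, 1, 1, 0, 1, 1, 0, 0, 1]
        rows = [dict(subject_id="s", age_group="adult", block=1,
                     block_type="adv", trial=t + 1, choice="risky",
                     outcome=20 if w else 0) for t, w in enumerate(wins)]
        df = pd.DataFrame(rows)
        alpha, beta, q1, kappa = 0.5, 1.0, 12.0, 1.0
        q, expected = q1, 0.0
        for w in wins:
            p = 1 / (1 + math.exp(-beta * (q - 10.0)))
            expected += math.log(p)
            q = q + alpha * ((20.0 if w else 0.0) - q)
        ll = log_likelihood(MODELS["m1c"],
                            ParamSet(alpha=alpha, kappa=kappa, beta=beta,
                                     q1=q1), df)
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_row_order(self):
        df = simulate_one("m1c", seed=5, alpha=0.3, kappa=1.3, beta=1.0,
                          q1=12.0)
        params = ParamSet(alpha=0.3, kappa=1.3, beta=1.0, q1=12.0)
        shuffled = df.sample(frac=1, random_state=1)
        assert log_likelihood(MODELS["m1c"], params, df) \
            == log_likelihood(MODELS["m1c"], params, shuffled)

    def test_incomplete_block_rejected(self):
        df = simulate_one("eps", seed=3, epsilon=0.5).iloc[:-1]
        with pytest.raises(ValueError, match="incomplete"):
            log_likelihood(MODELS["eps"], ParamSet(epsilon=0.5), df)


class TestCrossFamilyConsistency:
    def test_frozen_bio_rates_reproduce_rl_updates(self):
        """On a short win/loss run, injecting the BIO model's trial-specific
        effective rates into the delta rule reproduces its value estimates
        (both families implement the same mean update, at different rate
        schedules)."""
        spec = MODELS["m2a"]
        params = ParamSet(pi=1.0, beta=1.0, a1=1.0)
        state = init_belief(spec, params)
        q = 20.0 * state.a / (state.a + state.b)
        for won in (True, False, True):
            rate = effective_learning_rate(state, params.pi)
            q = q + rate * ((20.0 if won else 0.0) - q)
            state = bio_update(state, 20 if won else 0, params, spec)
            assert q == pytest.approx(risky_value(state, params, spec),
                                      abs=1e-12)


class TestSimulateAgent:
    def test_degenerate_rl_agent_is_indifferent(self):
        df = simulate_one("m1a", seed=11, alpha=0.0, beta=5.0, q1=10.0)
        assert len(df) == 200
        # Q pinned at the sure value: softmax indifference throughout
        assert abs((df["choice"] == "risky").mean() - 0.5) < 0.15

    def test_gf_agent_switches_after_wins(self):
        """Value drops after each win, so a gambler's-fallacy agent leaves
        the risky option right after it pays off."""
        switch_after_win, switch_after_loss = [], []
        for seed in range(25):
            df = simulate_one("gf_rl", seed=seed, alpha=-0.5, kappa=1.0,
                              beta=4.0, q1=12.0)
            for _, blk in df.groupby("block"):
                ch = blk["choice"].to_numpy()
                out = blk["outcome"].to_numpy()
                risky = ch[:-1] == "risky"
                win = risky & (out[:-1] == 20)
                loss = risky & (out[:-1] == 0)
                switch_after_win.extend((ch[1:] == "sure")[win])
                switch_after_loss.extend((ch[1:] == "sure")[loss])
        assert np.mean(switch_after_win) > np.mean(switch_after_loss)

    def test_sharp_bio_learner_converges_in_advantageous_blocks(self):
        # optimistic initial value (a1 > 1) keeps early exploration alive
        late = []
        for seed in range(60):
            df = simulate_one("m2b", seed=seed, pi_pos=1.0, pi_neg=1.0,
                              beta=8.0, a1=1.6)
            adv = df[(df["block_type"] == "adv") & (df["trial"] >= 16)]
            late.append((adv["choice"] == "risky").mean())
        assert np.mean(late) > 0.9
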