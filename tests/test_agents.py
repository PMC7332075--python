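import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twostep._likelihood import pack_session
from twostep.agents import (
    Agent,
    AgentParams,
    AgentState,
    ModelSpec,
    choice_probabilities,
    combine_hybrid,
    get_model,
    hybridplus_bonus,
    mf_update,
    ms_first_stage_values,
    prediction_error,
    transition_beliefs,
    update_transition_model,
)
from twostep.fitting import session_negloglik

from conftest import make_session


def state_with(q1=(0, 0), q2=((0, 0), (0, 0)), counts=(0, 0)):
    s = AgentState()
    s.q1 = np.array(q1, dtype=float)
    s.q2 = np.array(q2, dtype=float)
    s.counts = np.array(counts, dtype=float)
    return s


class TestPredictionError:
    def test_stage2_error_is_reward_minus_value(self):
        s = state_with(q2=((0.4, 0.0), (0.0, 0.0)))
        for variant in ("sarsa", "q"):
            d = prediction_error(variant, 2, s, 0, 0, 0, r2=1.0)
            assert d == pytest.approx(0.6)

    def test_stage1_sarsa_vs_q(self):
        # chosen second-stage value 0.8, unchosen 0.9, first-stage value 0.2
        s = state_with(q1=(0.2, 0.0), q2=((0.8, 0.9), (0.0, 0.0)))
        assert prediction_error("sarsa", 1, s, 0, 0, 0, 0.0) == pytest.approx(0.6)
        assert prediction_error("q", 1, s, 0, 0, 0, 0.0) == pytest.approx(0.7)

    def test_sarsa_self_consistency_gives_zero(self):
        s = state_with(q1=(0.5, 0.0), q2=((0.5, 0.1), (0.0, 0.0)))
        assert prediction_error("sarsa", 1, s, 0, 0, 0, 0.0) == 0.0


class TestMfUpdate:
    def test_learning_rate_arithmetic(self):
        s = state_with(q2=((0.5, 0.0), (0.0, 0.0)))
        p = AgentParams(alpha1=0.8, alpha2=0.8)
        mf_update(s, 0, 0, 0, delta1=0.0, delta2=0.5, params=p)
        assert s.q2[0, 0] == pytest.approx(0.9)

    def test_zero_learning_rate_is_inert(self):
        s = state_with(q1=(0.3, 0.1), q2=((0.5, 0.2), (0.1, 0.0)))
        before = (s.q1.copy(), s.q2.copy())
        mf_update(s, 0, 0, 0, 0.7, -0.2, AgentParams(alpha1=0.0, alpha2=0.0))
        assert np.allclose(s.q1, before[0]) and np.allclose(s.q2, before[1])

    def test_eligibility_trace_passes_stage2_error(self):
        s = state_with(q1=(0.2, 0.0))
        p = AgentParams(alpha1=0.5, alpha2=0.0, lam=0.5)
        mf_update(s, 0, 0, 0, delta1=0.0, delta2=0.4, params=p)
        assert s.q1[0] == pytest.approx(0.3)


class TestTransitionModel:
    def test_forward1_ignores_history(self):
        s = state_with()
        for _ in range(20):
            update_transition_model("forward1", s, 0, 1)
        p = transition_beliefs("forward1", s, 0)
        assert np.allclose(p, [0.7, 0.3])

    def test_forward2_majority_rule(self):
        s = state_with()
        for _ in range(7):
            update_transition_model("forward2", s, 0, 0)  # consistent
        for _ in range(3):
            update_transition_model("forward2", s, 0, 1)  # swapped
        p = transition_beliefs("forward2", s, 0)
        assert p[0] == pytest.approx(0.7)

    def test_forward2_tie_gives_uniform(self):
        s = state_with(counts=(4, 4))
        assert np.allclose(transition_beliefs("forward2", s, 0), [0.5, 0.5])

    def test_forward3_interpolates_with_evidence(self):
        s = state_with()
        p0 = transition_beliefs("forward3", s, 0, zeta=0.5)[0]
        s.counts = np.array([14.0, 6.0])
        p1 = transition_beliefs("forward3", s, 0, zeta=0.5)[0]
        assert 0.5 < p0 < p1 <= 0.7

    def test_beliefs_are_distributions(self):
        s = state_with(counts=(3, 9))
        for variant in ("forward1", "forward2", "forward3"):
            for a in (0, 1):
                p = transition_beliefs(variant, s, a)
                assert p.sum() == pytest.approx(1.0)
                assert np.all(p >= 0)


class TestFirstStageValues:
    def test_transition_weighted_maximum(self):
        s = state_with(q2=((1.0, 0.2), (0.0, 0.0)))
        v = ms_first_stage_values(s, "forward1")
        assert v[0] == pytest.approx(0.7)
        assert v[1] == pytest.approx(0.3)

    def test_equal_states_remove_transition_dependence(self):
        s = state_with(q2=((0.4, 0.1), (0.2, 0.4)))
        v = ms_first_stage_values(s, "forward1")
        assert v[0] == pytest.approx(v[1]) == pytest.approx(0.4)

    def test_hybrid_mixture(self):
        assert combine_hybrid([0.5], [1.0], 0.86)[0] == pytest.approx(0.93)
        q_mf, q_ms = np.array([0.3, 0.1]), np.array([0.9, 0.2])
        assert np.allclose(combine_hybrid(q_mf, q_ms, 0.0), q_mf)
        assert np.allclose(combine_hybrid(q_mf, q_ms, 1.0), q_ms)


class TestHybridPlusBonus:
    def test_common_high_boosts_previous_choice(self):
        p = AgentParams(L1=0.25)
        q = hybridplus_bonus(np.array([0.5, 0.5]), (True, 3, 0), p)
        assert q[0] == pytest.approx(0.75) and q[1] == pytest.approx(0.5)

    def test_rare_high_suppresses_previous_choice(self):
        p = AgentParams(L1=0.25)
        q = hybridplus_bonus(np.array([0.5, 0.5]), (False, 3, 0), p)
        assert q[0] == pytest.approx(0.25)

    def test_zero_boosts_match_plain_hybrid(self):
        q = np.array([0.4, 0.6])
        out = hybridplus_bonus(q, (True, 2, 1), AgentParams())
        assert np.allclose(out, q)

    def test_no_previous_trial_is_noop(self):
        q = np.array([0.1, 0.9])
        assert np.allclose(hybridplus_bonus(q, None, AgentParams(L1=5.0)), q)

    def test_mirrored_variant_touches_unchosen(self):
        p = AgentParams(L2=0.1)
        q = hybridplus_bonus(np.array([0.0, 0.0]), (True, 2, 1), p,
                             mirror_unchosen=True)
        assert q[1] == pytest.approx(0.1) and q[0] == pytest.approx(-0.1)


class TestChoiceRule:
    def test_zero_beta_is_uniform(self):
        p = choice_probabilities(np.array([5.0, -3.0]), 0.0, 0.4,
                                 np.array([1.0, 0.0]))
        assert np.allclose(p, [0.5, 0.5])

    def test_softmax_value(self):
        p = choice_probabilities(np.array([1.0, 0.0]), 1.0, 0.0, np.zeros(2))
        assert p[0] == pytest.approx(0.7311, abs=1e-4)

    def test_perseveration_bonus(self):
        p = choice_probabilities(np.array([0.5, 0.5]), 2.0, 0.3,
                                 np.array([1.0, 0.0]))
        assert p[0] == pytest.approx(0.6457, abs=1e-4)

    def test_guards_non_finite_values(self):
        with pytest.raises(FloatingPointError):
            choice_probabilities(np.array([np.nan, 0.0]), 1.0, 0.0, np.zeros(2))

    @given(
        q=st.tuples(st.floats(-5, 5), st.floats(-5, 5)),
        beta=st.floats(0, 20),
        kappa=st.floats(-3, 3),
    )
    @settings(max_examples=100, deadline=None)
    def test_probabilities_normalized(self, q, beta, kappa):
        p = choice_probabilities(np.array(q), beta, kappa,
                                 np.array([0.0, 1.0]))
        assert p.sum() == pytest.approx(1.0)
        assert np.all(p > 0) and np.all(p <= 1)


def _hand_sarsa_loglik(rows, alpha1, alpha2, beta1, beta2, kappa1, kappa2,
                       lam):
    """Independent plain-loop SARSA oracle over scripted trials."""
    q1 = [0.0, 0.0]
    q2 = [[0.0, 0.0], [0.0, 0.0]]
    last1 = None
    last2 = [None, None]
    total = 0.0
    max_juice = max(r[4] for r in rows)
    for a1, s2, a2, level, juice in rows:
        r2 = juice / max_juice
        z = [beta1 * (q1[a] + (kappa1 if last1 == a else 0.0)) for a in (0, 1)]
        total += z[a1] - math.log(math.exp(z[0]) + math.exp(z[1]))
        z = [beta2 * (q2[s2][a] + (kappa2 if last2[s2] == a else 0.0))
             for a in (0, 1)]
        total += z[a2] - math.log(math.exp(z[0]) + math.exp(z[1]))
        d1 = q2[s2][a2] - q1[a1]
        d2 = r2 - q2[s2][a2]
        q1[a1] += alpha1 * d1
        q2[s2][a2] += alpha2 * d2
        q1[a1] += alpha1 * lam * d2
        last1, last2[s2] = a1, a2
    return total


class TestAgentTrialStep:
    ROWS = [
        (0, 0, 0, 3, 900.0),
        (0, 1, 1, 1, 0.0),
        (1, 1, 0, 2, 300.0),
        (1, 0, 1, 3, 800.0),
        (0, 0, 0, 2, 250.0),
    ]

    def test_matches_hand_rolled_sarsa_loop(self):
        params = dict(alpha1=0.6, alpha2=0.4, beta1=2.0, beta2=1.5,
                      kappa1=0.2, kappa2=-0.1, lam=0.3)
        expected = -_hand_sarsa_loglik(self.ROWS, **params)
        sess = make_session(self.ROWS)
        nll = session_negloglik(AgentParams(**params), sess,
                                get_model("sarsa"), use_kernel=False)
        assert nll == pytest.approx(expected, abs=1e-12)

    def test_forced_first_stage_contributes_probability_one(self):
        rows = list(self.ROWS)
        sess_free = make_session(rows)
        rows_forced = [
            (*rows[0], {"forced_stage": 1}),
            *rows[1:],
        ]
        sess_forced = make_session(rows_forced)
        spec = get_model("sarsa")
        p = AgentParams(alpha1=0.5, alpha2=0.5, beta1=2.0, beta2=2.0)
        nll_free = session_negloglik(p, sess_free, spec, use_kernel=False)
        nll_forced = session_negloglik(p, sess_forced, spec, use_kernel=False)
        # trial 0 is symmetric (all Q equal) so its stage-1 logp is log(0.5)
        assert nll_free - nll_forced == pytest.approx(np.log(2.0), abs=1e-12)

    def test_lambda_inert_when_pure_ms(self):
        spec = ModelSpec(name="ms", mf_variant=None, ms_variant="forward1")
        sess = make_session(self.ROWS)
        base = dict(alpha2=0.5, beta1=2.0, beta2=1.0)
        a = session_negloglik(spec.expand([0.5, 2.0, 1.0, 0.1, 0.0]),
                              sess, spec, use_kernel=False)
        # lam lives outside the free set; setting it on AgentParams directly
        p = AgentParams(alpha2=0.5, beta1=2.0, beta2=1.0, kappa1=0.1,
                        omega=1.0, lam=0.9)
        b = session_negloglik(p, sess, spec, use_kernel=False)
        assert a == pytest.approx(b, abs=1e-12)

    def test_hybrid_omega_limits_reproduce_pure_models(self):
        sess = make_session(self.ROWS)
        hybrid = ModelSpec(name="h", mf_variant="sarsa", ms_variant="forward1")
        base = dict(alpha1=0.6, alpha2=0.4, beta1=2.0, beta2=1.5,
                    kappa1=0.2, kappa2=-0.1, lam=0.3)
        mf_nll = session_negloglik(AgentParams(**base), sess,
                                   get_model("sarsa"), use_kernel=False)
        h0 = session_negloglik(AgentParams(**base, omega=0.0), sess, hybrid,
                               use_kernel=False)
        assert h0 == pytest.approx(mf_nll, abs=1e-12)
        ms = ModelSpec(name="ms", mf_variant=None, ms_variant="forward1")
        ms_nll = session_negloglik(
            AgentParams(alpha2=0.4, beta1=2.0, beta2=1.5, kappa1=0.2,
                        kappa2=-0.1, omega=1.0),
            sess, ms, use_kernel=False)
        h1 = session_negloglik(
            AgentParams(alpha1=0.6, alpha2=0.4, beta1=2.0, beta2=1.5,
                        kappa1=0.2, kappa2=-0.1, lam=0.3, omega=1.0),
            sess, hybrid, use_kernel=False)
        assert h1 == pytest.approx(ms_nll, abs=1e-12)

    def test_inconsistent_transition_label_raises(self):
        sess = make_session(self.ROWS)
        sess.trials[3].transition = "common"  # contradicts s2 != a1
        with pytest.raises(ValueError):
            session_negloglik(AgentParams(), sess, get_model("sarsa"),
                              use_kernel=False)


class TestQBounds:
    @given(
        alpha1=st.floats(0.01, 1.0), alpha2=st.floats(0.01, 1.0),
        lam=st.floats(0.0, 1.0), seed=st.integers(0, 1000),
    )
    @settings(max_examples=30, deadline=None)
    def test_values_stay_in_unit_interval(self, alpha1, alpha2, lam, seed):
        rng = np.random.default_rng(seed)
        agent = Agent(
            AgentParams(alpha1=alpha1, alpha2=alpha2, lam=lam, beta1=1.0,
                        beta2=1.0),
            get_model("sarsa"),
        )
        for i in range(100):
            a1 = int(rng.integers(2))
            s2 = int(rng.integers(2))
            a2 = int(rng.integers(2))
            r2 = float(rng.random())
            agent._learn(a1, s2, a2, int(rng.integers(1, 4)), r2)
            assert np.all(agent.state.q1 >= -1e-12)
            assert np.all(agent.state.q1 <= 1 + 1e-12)
            assert np.all(agent.state.q2 >= -1e-12)
            assert np.all(agent.state.q2 <= 1 + 1e-12)


class TestModelSpec:
    def test_registry_free_parameter_counts(self):
        assert get_model("sarsa").n_free == 7
        assert get_model("forward1").n_free == 4
        assert get_model("forward3").n_free == 5
        assert get_model("hybrid").n_free == 5
        assert get_model("hybrid_plus").n_free == 8

    def test_expand_respects_ties_and_fixed_values(self):
        spec = get_model("hybrid_plus")
        vals = dict(zip(spec.free_params, spec.shrink(spec.expand(
            [0.8, 4.0, 2.5, 0.05, 0.86, 0.25, -0.06, -0.08][: spec.n_free]
        ))))
        p = spec.expand([0.8, 4.0, 2.5, 0.05, 0.86, 0.25, -0.06, -0.08,
                         0.0][: spec.n_free])
        assert p.alpha2 == p.alpha1
        assert p.kappa2 == p.kappa1
        assert p.lam == 0.0

    def test_pure_specs_pin_omega(self):
        assert get_model("sarsa").expand([0.5] * 4 + [0.0] * 3).omega == 0.0
        assert get_model("forward1").expand([0.5, 1.0, 1.0, 0.0]).omega == 1.0

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(mf_variant="sarsa", ms_variant=None, hybrid_plus=True)
        with pytest.raises(ValueError):
            ModelSpec(mf_variant=None, ms_variant=None)
        with pytest.raises(ValueError):
            ModelSpec(mf_variant="tdzero")
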