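import numpy as np
import pandas as pd
import pytest

from twostep.behaviour import (
    build_choice_design,
    build_rt_design,
    contrast_ttest,
    fit_decay,
    fit_linear_fixed,
    fit_logistic_fixed,
    fit_mixed_regression,
    preprocess_rt,
    stay_table,
)
from twostep.task import SessionData, TrialRecord

from conftest import make_session, make_trial


def _random_session(rng, n=400, session_id="s0", rt_slope=0.0):
    """Session with i.i.d. random choices/outcomes and lognormal RTs."""
    rows = []
    prev_r = 2.0
    for i in range(n):
        a1 = int(rng.integers(2))
        s2 = int(rng.integers(2)) if rng.random() < 0.5 else a1
        a2 = int(rng.integers(2))
        level = int(rng.integers(1, 4))
        juice = 0.0 if level == 1 else 300.0 * level
        rows.append((a1, s2, a2, level, juice))
    sess = make_session(rows, session_id=session_id)
    for i, t in enumerate(sess.trials):
        mu = 6.0 + 0.1 * t.side1 + rt_slope * (prev_r - 2.0)
        t.rt1 = float(np.exp(rng.normal(mu, 0.2)))
        t.fix_rt = float(np.exp(rng.normal(5.5, 0.2)))
        t.side1 = int(rng.integers(3))
        prev_r = t.outcome_level
    return sess


class TestStayTable:
    def test_always_repeat_agent_hits_one(self):
        rows = [(0, 0, 0, 3, 500.0)] * 10 + [(0, 1, 0, 1, 0.0)] * 5
        tab = stay_table([make_session(rows)])
        vals = tab["per_session"].iloc[0]
        assert vals[(3, "common")] == 1.0
        assert np.isnan(vals[(3, "rare")])  # never observed

    def test_hand_counted_frequencies(self):
        # pairs: (3,common)->repeat, (1,rare)->switch, (2,common)->switch,
        #        (3,common)->repeat, (1,rare)->repeat
        rows = [
            (0, 0, 0, 3, 500.0),
            (0, 1, 0, 1, 0.0),
            (1, 1, 0, 2, 300.0),
            (0, 0, 1, 3, 450.0),
            (0, 1, 1, 1, 0.0),
            (0, 0, 0, 2, 250.0),
        ]
        tab = stay_table([make_session(rows)])
        vals = tab["per_session"].iloc[0]
        assert vals[(3, "common")] == 1.0
        assert vals[(1, "rare")] == 0.5
        assert vals[(2, "common")] == 0.0

    def test_excluded_trials_do_not_form_pairs(self):
        rows = [
            (0, 0, 0, 3, 500.0),
            (0, 0, 0, 3, 500.0, {"forced_stage": 1}),
            (1, 1, 1, 2, 300.0),
        ]
        tab = stay_table([make_session(rows)])
        vals = tab["per_session"].iloc[0]
        # the forced middle trial is removed; the remaining pair is a switch
        assert vals[(3, "common")] == 0.0


class TestChoiceDesign:
    def test_reward_centering_and_scaling(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(300):
            level = (i % 3) + 1  # exactly equal frequencies
            rows.append((int(rng.integers(2)), 0, 0, level,
                         0.0 if level == 1 else 100.0 * level))
        # make transitions consistent
        sess = make_session([(a1, a1, a2, l, j) for a1, _, a2, l, j in rows])
        design = build_choice_design([sess], n_lags=1)
        r = np.sort(np.unique(np.round(design.X["R_t-1"], 4)))
        assert np.allclose(r, [-0.6124, 0.0, 0.6124], atol=1e-3)

    def test_column_count_and_burn_in(self):
        rng = np.random.default_rng(1)
        sess = _random_session(rng, n=10)
        design = build_choice_design([sess], n_lags=5)
        assert design.X.shape == (5, 36)
        assert design.columns[0] == "const"

    def test_degenerate_column_flagged(self):
        rows = [(i % 2, i % 2, 0, 2, 300.0) for i in range(20)]  # all common
        design = build_choice_design([make_session(rows)], n_lags=1)
        assert any(c.startswith("T_") for c in design.degenerate_columns)

    def test_short_session_yields_empty_design(self):
        rows = [(0, 0, 0, 2, 300.0)] * 4
        design = build_choice_design([make_session(rows)], n_lags=5)
        assert design.X.empty


class TestLogisticFixed:
    def test_null_design_coefficients_cover_zero(self):
        rng = np.random.default_rng(2)
        sessions = [_random_session(rng, n=1300, session_id=f"s{i}")
                    for i in range(4)]
        design = build_choice_design(sessions, n_lags=1)
        res = fit_logistic_fixed(design)
        terms = [c for c in res.mean.index if c != "const"]
        # with random choices no predictor should be reliably non-zero
        assert (res.pvalue[terms] < 0.01).sum() == 0

    def test_known_logit_weights_recovered(self):
        rng = np.random.default_rng(3)
        sessions = []
        for s in range(3):
            rows = []
            prev = 0
            for i in range(1500):
                # choice depends on previous C (centred) with weight 1.5
                logit = 1.5 * (prev - 0.5) * 2
                p = 1 / (1 + np.exp(-logit))
                c = int(rng.random() < p)
                a1 = 0 if c else 1
                s2 = a1 if rng.random() < 0.7 else 1 - a1
                level = int(rng.integers(1, 4))
                rows.append((a1, s2, int(rng.integers(2)), level,
                             0.0 if level == 1 else 200.0 * level))
                prev = c
            sessions.append(make_session(rows, session_id=f"s{s}"))
        design = build_choice_design(sessions, n_lags=1)
        res = fit_logistic_fixed(design)
        # C was centred (range 1) with true weight 3 per unit of C
        assert res.mean["C_t-1"] == pytest.approx(3.0, abs=3 * res.se["C_t-1"]
                                                  + 0.3)

    def test_contrast_test_runs(self):
        rng = np.random.default_rng(4)
        sessions = [_random_session(rng, n=600, session_id=f"s{i}")
                    for i in range(3)]
        res = fit_logistic_fixed(build_choice_design(sessions, n_lags=1))
        t, p = contrast_ttest(res, "RxC_t-1", "RxTxC_t-1")
        assert np.isfinite(t) and 0 <= p <= 1


class TestRtPipeline:
    def test_zscores_centred_per_side(self):
        rng = np.random.default_rng(5)
        sess = _random_session(rng, n=600)
        z = preprocess_rt(sess, "rt1")
        sides = {t.trial_index: t.side1 for t in sess.trials}
        frame = pd.DataFrame({"z": z, "side": [sides[i] for i in z.index]})
        for _, grp in frame.dropna().groupby("side"):
            assert abs(grp["z"].mean()) < 0.1

    def test_outlier_removed_by_three_sd_rule(self):
        rng = np.random.default_rng(6)
        sess = _random_session(rng, n=300)
        victim = next(t for t in sess.trials
                      if not t.is_error and t.forced_stage == 0)
        victim.rt1 = victim.rt1 * 10
        z = preprocess_rt(sess, "rt1")
        assert np.isnan(z.get(victim.trial_index, np.nan))

    def test_rank_order_preserved_within_side(self):
        rng = np.random.default_rng(7)
        sess = _random_session(rng, n=200)
        z = preprocess_rt(sess, "rt1")
        raw = {t.trial_index: (t.rt1, t.side1) for t in sess.trials}
        frame = pd.DataFrame(
            {"z": z,
             "rt": [raw[i][0] for i in z.index],
             "side": [raw[i][1] for i in z.index]}
        ).dropna()
        for _, grp in frame.groupby("side"):
            assert grp.sort_values("rt")["z"].is_monotonic_increasing

    def test_rt_design_shape(self):
        rng = np.random.default_rng(8)
        sess = _random_session(rng, n=60)
        design = build_rt_design([sess], n_lags=5)
        assert design.X.shape[1] == 17
        assert "F" in design.columns

    def test_linear_recovery_of_lagged_reward_effect(self):
        rng = np.random.default_rng(9)
        sessions = [_random_session(rng, n=1200, session_id=f"s{i}",
                                    rt_slope=-0.2) for i in range(3)]
        design = build_rt_design(sessions, n_lags=2)
        res = fit_linear_fixed(design)
        assert res.mean["R_t-1"] < 0
        assert res.pvalue["R_t-1"] < 0.05


class TestDecayFit:
    def test_exact_exponential_recovery(self):
        lags = np.arange(1, 6)
        c = 0.9 * np.exp(-0.78 * lags)
        fit = fit_decay(c)
        assert fit.decay == pytest.approx(-0.78, abs=1e-6)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_input_gives_zero_decay(self):
        fit = fit_decay([0.4] * 5)
        assert fit.decay == 0.0

    def test_noisy_recovery(self):
        rng = np.random.default_rng(10)
        lags = np.arange(1, 6)
        truth = -0.9
        c = 0.8 * np.exp(truth * lags) + rng.normal(0, 0.08 * 0.8, 5)
        fit = fit_decay(c)
        assert fit.decay == pytest.approx(truth, abs=0.3)

    def test_idempotence_on_fitted_values(self):
        fit = fit_decay([0.5, 0.3, 0.22, 0.12, 0.08])
        refit = fit_decay(fit.fitted)
        assert refit.amplitude == pytest.approx(fit.amplitude, abs=1e-6)
        assert refit.decay == pytest.approx(fit.decay, abs=1e-6)

    def test_sign_alternating_input_returns_low_r2(self):
        fit = fit_decay([0.5, -0.4, 0.3, -0.2, 0.1])
        assert fit.adj_r2 < 0.5  # no error raised


class TestMixedRegression:
    def test_shared_truth_matches_pooled_estimate(self):
        rng = np.random.default_rng(11)
        sessions = [_random_session(rng, n=900, session_id=f"s{i}")
                    for i in range(4)]
        design = build_choice_design(sessions, n_lags=1)
        fixed = fit_logistic_fixed(design)
        mixed = fit_mixed_regression(design, family="logistic")
        for term in ("C_t-1", "R_t-1"):
            assert mixed.mean[term] == pytest.approx(
                fixed.mean[term], abs=3 * fixed.se[term] + 0.05
            )

    def test_shrinkage_toward_population_mean(self):
        rng = np.random.default_rng(12)
        sessions = [_random_session(rng, n=250, session_id=f"s{i}")
                    for i in range(6)]
        design = build_choice_design(sessions, n_lags=1)
        fixed = fit_logistic_fixed(design)
        mixed = fit_mixed_regression(design, family="logistic")
        # mixed SEs must not exceed the naive across-session spread wildly
        assert (mixed.se <= fixed.se * 3 + 0.5).all()
        assert mixed.method == "mixed"

    def test_requires_two_sessions(self):
        rng = np.random.default_rng(13)
        design = build_choice_design([_random_session(rng, n=200)], n_lags=1)
        with pytest.raises(ValueError):
            fit_mixed_regression(design)
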