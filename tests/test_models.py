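import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from learnarb.models import (MODEL_ORDER, NormalizationPolicy,
                             arbitration_weight, baseline_choice_prob,
                             combined_choice_prob, el_choice_prob, el_step,
                             get_model, model_nll, ol_choice_prob, ol_step,
                             reliability_el, reliability_ol, simulate_choices,
                             trace_nll)
from learnarb.recovery import default_param_sampler
from learnarb.session import Session
from learnarb.task import TaskConfig, generate_session


def logistic(z):
    return 1.0 / (1.0 + math.exp(-z))


class TestExperientialOps:
    def test_delta_rule_arithmetic(self):
        v, m_or, m_bl, erpe = el_step(0.5, 0.0, 0.0, choice=1, rewarded=True,
                                      outcome_points=50, alpha_exp=0.5)
        assert v == pytest.approx(0.75)
        assert erpe == pytest.approx(0.5)
        # unchosen value is the complement
        assert 1.0 - v == pytest.approx(0.25)

    def test_zero_learning_rate_is_identity(self):
        v, *_ = el_step(0.37, 5.0, 3.0, 1, True, 90, alpha_exp=0.0)
        assert v == pytest.approx(0.37)

    def test_magnitude_tracker_decay(self):
        # orange chosen and unrewarded halves its tracker; unchosen blue halves
        _, m_or, m_bl, _ = el_step(0.5, 40.0, 12.0, choice=1, rewarded=False,
                                   outcome_points=0, alpha_exp=0.3)
        assert m_or == pytest.approx(20.0)
        assert m_bl == pytest.approx(6.0)

    def test_magnitude_tracker_set_on_reward(self):
        _, m_or, m_bl, _ = el_step(0.5, 40.0, 12.0, choice=1, rewarded=True,
                                   outcome_points=77, alpha_exp=0.3)
        assert m_or == 77.0 and m_bl == 6.0

    @pytest.mark.parametrize("v,m_or,m_bl,beta,mu,expected", [
        (0.5, 0.0, 0.0, 4.0, 0.0, 0.5),
        (0.75, 0.0, 0.0, 4.0, 0.0, logistic(2.0)),       # value diff 0.5
        (0.5, 50.0, 0.0, 0.0, 0.02, logistic(1.0)),       # magnitude only
    ])
    def test_choice_probability(self, v, m_or, m_bl, beta, mu, expected):
        assert el_choice_prob(v, m_or, m_bl, beta, mu) == pytest.approx(expected)


class TestObservationalOps:
    def test_update_arithmetic(self):
        a, b, ospe, tokv = ol_step(0.5, 0.5, partner_box=0, observed_token=1,
                                   alpha_obs=0.8)
        assert a == pytest.approx(0.9)
        assert b == pytest.approx(0.1)
        assert ospe == pytest.approx(0.5)
        assert tokv == pytest.approx(0.9)

    def test_zero_learning_rate_is_identity(self):
        a, b, *_ = ol_step(0.3, 0.7, 1, 0, alpha_obs=0.0)
        assert (a, b) == (0.3, 0.7)

    def test_full_rate_pins_values_after_two_observations(self):
        # two consecutive identical (box, token) observations at alpha=1
        a, b, *_ = ol_step(0.5, 0.5, 0, 1, alpha_obs=1.0)
        a, b, *_ = ol_step(a, b, 0, 1, alpha_obs=1.0)
        assert a == 1.0 and b == 0.0

    @pytest.mark.parametrize("tokv,beta,expected", [
        (0.5, 5.0, 0.5),
        (0.9, 5.0, logistic(4.0)),
        (0.13, 0.0, 0.5),
    ])
    def test_choice_probability(self, tokv, beta, expected):
        assert ol_choice_prob(tokv, beta) == pytest.approx(expected)


class TestArbitrationOps:
    @pytest.mark.parametrize("ospe,expected", [
        (0.0, 1.0), (1.0, -1.0), (0.25, 0.5), (-0.25, 0.5),
    ])
    def test_ol_reliability(self, ospe, expected):
        assert reliability_ol(ospe) == pytest.approx(expected)

    @pytest.mark.parametrize("erpe,outcome,expected", [
        (0.0, 99.0, 0.99), (1.0, 0.0, -1.0), (0.5, 50.0, 0.0),
    ])
    def test_el_reliability(self, erpe, outcome, expected):
        assert reliability_el(erpe, outcome) == pytest.approx(expected)

    def test_degenerate_bounds_warn_and_zero(self):
        pol = NormalizationPolicy(ospe_bounds=(0.3, 0.3))
        with pytest.warns(UserWarning):
            assert reliability_ol(0.5, pol) == 0.0

    @pytest.mark.parametrize("r_ol,r_el,delta,expected", [
        (0.4, 0.4, 0.0, 0.5),
        (1.0, -1.0, 0.0, logistic(2.0)),
        (0.0, 0.0, 30.0, logistic(30.0)),
    ])
    def test_arbitration_weight(self, r_ol, r_el, delta, expected):
        assert arbitration_weight(r_ol, r_el, delta) == pytest.approx(expected)

    @pytest.mark.parametrize("p_obs,p_exp,omega,expected", [
        (0.7, 0.2, 1.0, 0.7), (0.7, 0.2, 0.0, 0.2), (0.9, 0.1, 0.5, 0.5),
    ])
    def test_mixture(self, p_obs, p_exp, omega, expected):
        assert combined_choice_prob(p_obs, p_exp, omega) == pytest.approx(expected)


class TestBaselineOps:
    def test_null_model_is_uniform(self):
        assert baseline_choice_prob(1, None, 0, 0, 0, 0, 0) == 0.5

    def test_color_bias_ignores_history(self):
        for ol, ps in [(0, 0), (1, 1), (0, 1)]:
            p = baseline_choice_prob(ol, 1, ps, 2.0, 0.0, 0.0, 0.0)
            assert p == pytest.approx(logistic(2.0))

    def test_side_bias(self):
        p = baseline_choice_prob(1, None, 0, 0.0, 1.0, 0.0, 0.0)
        assert p == pytest.approx(logistic(1.0))

    def test_sticky_term_undefined_on_first_trial(self):
        p = baseline_choice_prob(1, None, 1, 0.0, 0.0, 5.0, 0.0)
        assert p == 0.5


class TestLikelihood:
    def test_uniform_limit_all_models(self, random_session):
        n = random_session.n_trials
        zero = {
            "baseline": dict(b_color=0, b_side=0, b_sticky=0, b_imit=0),
            "el": dict(alpha_exp=0.5, beta_exp=0.0, mu=0.0),
            "ol": dict(alpha_obs=0.5, beta_obs=0.0),
            "fixmix": dict(alpha_exp=0.5, beta_exp=0.0, mu=0.0,
                           alpha_obs=0.5, beta_obs=0.0, omega=0.3),
            "dynarb": dict(alpha_exp=0.5, beta_exp=0.0, mu=0.0,
                           alpha_obs=0.5, beta_obs=0.0, delta=0.7),
        }
        for name, params in zero.items():
            assert model_nll(random_session, name, params) == pytest.approx(
                n * math.log(2))

    def test_single_trial_probability(self, random_session):
        # a color-bias-only baseline assigns logistic(b) to orange
        one = Session(random_session.trials.iloc[:1].copy())
        params = dict(b_color=math.log(4), b_side=0, b_sticky=0, b_imit=0)
        want = 0.8 if one.trials.iloc[0]["choice"] == "orange" else 0.2
        assert model_nll(one, "baseline", params) == pytest.approx(-math.log(want))

    def test_mixture_nests_single_strategies(self, dynarb_session):
        el = dict(alpha_exp=0.4, beta_exp=3.0, mu=0.01)
        ol = dict(alpha_obs=0.6, beta_obs=4.0)
        full = {**el, **ol}
        nll_el = model_nll(dynarb_session, "el", el)
        nll_ol = model_nll(dynarb_session, "ol", ol)
        assert model_nll(dynarb_session, "fixmix",
                         {**full, "omega": 0.0}) == pytest.approx(nll_el)
        assert model_nll(dynarb_session, "fixmix",
                         {**full, "omega": 1.0}) == pytest.approx(nll_ol)

    def test_dynamic_reduces_to_fixed_under_equal_reliability(self, config):
        # on a never-rewarded session with degenerate normalization bounds
        # both reliabilities are 0, so omega_t == logistic(delta) throughout
        s = generate_session(config, agent="random",
                             rng=np.random.default_rng(42), list_index=2)
        df = s.trials.copy()
        df["outcome"] = 0
        s0 = Session(df)
        shared = dict(alpha_exp=0.4, beta_exp=3.0, mu=0.01,
                      alpha_obs=0.6, beta_obs=4.0)
        delta = 0.8
        degenerate = NormalizationPolicy(ospe_bounds=(0.0, 0.0),
                                         erpe_bounds=(0.0, 0.0))
        with pytest.warns(UserWarning):
            nll_dyn, _ = trace_nll(s0, "dynarb", {**shared, "delta": delta},
                                   norm=degenerate)
        nll_fix = model_nll(s0, "fixmix",
                            {**shared, "omega": logistic(delta)})
        assert nll_dyn == pytest.approx(nll_fix, abs=1e-9)

    def test_fast_and_incremental_paths_agree(self, dynarb_session):
        rng = np.random.default_rng(6)
        for name in MODEL_ORDER:
            for _ in range(3):
                params = default_param_sampler(name, rng)
                fast = model_nll(dynarb_session, name, params)
                slow, trace = trace_nll(dynarb_session, name, params)
                assert fast == pytest.approx(slow, abs=1e-10)
                assert len(trace) == dynarb_session.n_trials

    def test_missing_choices_skipped_but_observed(self, random_session):
        df = random_session.trials.copy()
        missing = df.index[10:40]
        df.loc[missing, "choice"] = ""
        df.loc[missing, "outcome"] = 0
        s = Session(df)
        n_scored = (df["choice"] != "").sum()
        params = dict(b_color=0, b_side=0, b_sticky=0, b_imit=0)
        assert model_nll(s, "baseline", params) == pytest.approx(
            n_scored * math.log(2))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           model=st.sampled_from(MODEL_ORDER))
    def test_trace_invariants(self, dynarb_session, seed, model):
        """Latent probabilities stay in range and complements are exact."""
        rng = np.random.default_rng(seed)
        params = default_param_sampler(model, rng)
        nll, tr = trace_nll(dynarb_session, model, params)
        assert np.isfinite(nll)
        p = tr["P_or"].to_numpy()
        assert ((p > 0) & (p < 1)).all()
        assert np.allclose(tr["TokV_exp_or"] + tr["TokV_exp_bl"], 1.0)
        assert np.allclose(tr["TokV_obs_or"] + tr["TokV_obs_bl"], 1.0)
        if model != "baseline":
            assert tr["ActV_obs_A"].between(0, 1).all()
            assert tr["oSPE"].abs().le(1).all()
            assert tr["eRPE"].abs().max() <= 1 or tr["eRPE"].isna().all()
        if model == "dynarb":
            assert tr["R_OL"].between(-1, 1).all()
            assert tr["R_EL"].between(-1, 1).all()
            assert tr["omega_t"].between(0, 1).all()


class TestSimulateChoices:
    def test_uniform_baseline_frequency(self, config):
        big = TaskConfig(n_blocks=5, trials_per_block=2000,
                         reversal_window=(900, 1100))
        s = generate_session(big, agent="random",
                             rng=np.random.default_rng(8))
        sim = simulate_choices(s, "baseline",
                               dict(b_color=0, b_side=0, b_sticky=0, b_imit=0),
                               np.random.default_rng(9))
        freq = (sim.trials["choice"] == "orange").mean()
        assert abs(freq - 0.5) < 0.02

    def test_greedy_observer_tracks_partner_goal(self, random_session):
        # near-deterministic OL: after observing the partner, the simulated
        # choice matches the model's inferred goal token almost always
        sim = simulate_choices(random_session, "ol",
                               dict(alpha_obs=1.0, beta_obs=30.0),
                               np.random.default_rng(10))
        _, tr = trace_nll(sim, "ol", dict(alpha_obs=1.0, beta_obs=30.0))
        arr = sim.arrays()
        goal = (tr["TokV_obs_or"].to_numpy() > 0.5).astype(int)
        decided = tr["TokV_obs_or"].to_numpy() != 0.5
        agree = np.mean(arr.choice[decided] == goal[decided])
        assert agree > 0.95

    def test_replay_keeps_partner_stream(self, dynarb_session):
        sim = simulate_choices(dynarb_session, "el",
                               dict(alpha_exp=0.5, beta_exp=5.0, mu=0.0),
                               np.random.default_rng(13))
        a, b = dynarb_session.trials, sim.trials
        assert (a["partner_box"] == b["partner_box"]).all()
        assert (a["observed_token"] == b["observed_token"]).all()
        assert (a["rew_prob_orange"] == b["rew_prob_orange"]).all()
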