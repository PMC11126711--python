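import numpy as np
import pandas as pd
import pytest

from learnarb.session import Session
from learnarb.signatures import (arbitration_index, build_glm_design,
                                 fit_me_glm, label_trials, learning_curve,
                                 ol_choice_propensity, signature_report)
from learnarb.task import TaskConfig, generate_cohort, generate_session


@pytest.fixture(scope="module")
def labelled(random_session=None):
    cfg = TaskConfig()
    s = generate_session(cfg, agent="random", rng=np.random.default_rng(60),
                         list_index=4)
    return s, label_trials(s)


class TestLabels:
    def test_el_consistent_follows_reward(self, labelled):
        s, lab = labelled
        arr = s.arrays()
        for t in range(1, s.n_trials):
            want = -1
            if arr.choice[t - 1] >= 0:
                want = (arr.choice[t - 1] if arr.rewarded[t - 1]
                        else 1 - arr.choice[t - 1])
            assert lab["el_consistent"].iloc[t] == want

    def test_ol_consistent_repeat_and_switch(self, labelled):
        s, lab = labelled
        arr = s.arrays()
        for t in range(1, s.n_trials):
            if arr.block_start[t]:
                assert lab["ol_consistent"].iloc[t] == -1
                continue
            tok = arr.observed_token[t - 1]
            want = tok if arr.partner_box[t] == arr.partner_box[t - 1] \
                else 1 - tok
            assert lab["ol_consistent"].iloc[t] == want

    @pytest.mark.parametrize("w2,stay,w1,low", [
        (1, True, 1, True),    # win-stay-win
        (1, False, 0, True),   # win-shift-loss
        (0, True, 0, True),    # loss-stay-loss
        (0, False, 1, True),   # loss-shift-win
        (1, True, 0, False),   # win-stay-loss
        (0, True, 1, False),
        (1, False, 1, False),
        (0, False, 0, False),
    ])
    def test_el_uncertainty_patterns(self, w2, stay, w1, low):
        rows = []
        choices = ["orange", "orange" if stay else "blue", "orange"]
        outs = [50 * w2, 50 * w1, 0]
        for t in range(3):
            rows.append((0, t, "A", "left", "orange", choices[t], outs[t],
                         "left", 0.8, 0.8, "narrow", 0))
        df = pd.DataFrame(rows, columns=[
            "block", "trial", "partner_box", "partner_side", "observed_token",
            "choice", "outcome", "orange_side", "trans_prob",
            "rew_prob_orange", "mag_regime", "reversal"])
        lab = label_trials(Session(df))
        assert lab["el_unc"].iloc[2] == (0 if low else 1)

    def test_ol_uncertainty_consistency(self, labelled):
        s, lab = labelled
        arr = s.arrays()
        for t in range(s.n_trials):
            if lab["ol_unc"].iloc[t] == -1:
                continue
            same_box = arr.partner_box[t - 1] == arr.partner_box[t - 2]
            same_tok = arr.observed_token[t - 1] == arr.observed_token[t - 2]
            assert lab["ol_unc"].iloc[t] == int(same_box != same_tok)

    def test_magnitude_threshold(self, labelled):
        s, lab = labelled
        arr = s.arrays()
        for t in range(1, s.n_trials):
            if arr.choice[t - 1] >= 0:
                assert lab["magnitude"].iloc[t] == int(arr.outcome[t - 1] > 25)

    def test_labels_are_causal(self, labelled):
        s, lab = labelled
        half = Session(s.trials.iloc[:80].copy())
        lab_half = label_trials(half)
        assert lab_half.equals(lab.iloc[:80].reset_index(drop=True))


class TestPropensity:
    def _rule_following_session(self, follow, seed=61):
        """Generate a session whose choices follow el/ol-consistency."""
        cfg = TaskConfig()
        base = generate_session(cfg, agent="random",
                                rng=np.random.default_rng(seed), list_index=6)
        df = base.trials.copy()
        # choose causally: labels at t depend only on trials < t
        for t in range(len(df)):
            lab = label_trials(Session(df))
            want = lab[follow].iloc[t]
            if want >= 0:
                df.loc[df.index[t], "choice"] = "orange" if want else "blue"
        return Session(df)

    def test_pure_observational_follower(self):
        s = self._rule_following_session("ol_consistent")
        prop, n = ol_choice_propensity(s, label_trials(s))
        assert n > 0 and prop == 1.0

    def test_pure_experiential_follower(self):
        s = self._rule_following_session("el_consistent")
        prop, n = ol_choice_propensity(s, label_trials(s))
        assert n > 0 and prop == 0.0

    def test_random_chooser_near_half(self):
        cfg = TaskConfig(n_blocks=8, trials_per_block=200,
                         reversal_window=(80, 120))
        s = generate_session(cfg, agent="random",
                             rng=np.random.default_rng(62))
        prop, n = ol_choice_propensity(s, label_trials(s))
        assert n > 200
        assert abs(prop - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_empty_cell_returns_nan(self, labelled):
        s, lab = labelled
        prop, n = ol_choice_propensity(s, lab,
                                       mask=np.zeros(s.n_trials, bool))
        assert n == 0 and np.isnan(prop)


class TestLearningCurve:
    def test_always_correct_agent(self, labelled):
        s, _ = labelled
        df = s.trials.copy()
        df["choice"] = np.where(df["rew_prob_orange"] > 0.5, "orange", "blue")
        curve = learning_curve(Session(df))
        assert np.allclose(curve, 1.0)

    def test_random_agent_flat_at_half(self):
        cfg = TaskConfig(n_blocks=40, trials_per_block=20,
                         reversal_window=(8, 13))
        s = generate_session(cfg, agent="random",
                             rng=np.random.default_rng(63))
        curve = learning_curve(s)
        assert np.nanmax(np.abs(curve - 0.5)) < 0.15

    def test_no_reversals_rejected(self, labelled):
        s, _ = labelled
        df = s.trials.copy()
        df["rew_prob_orange"] = 0.8
        with pytest.raises(ValueError):
            learning_curve(Session(df))

    def test_curve_has_eight_points(self, dynarb_session):
        assert len(learning_curve(dynarb_session)) == 8


class TestGLMDesign:
    def test_out_coding(self, labelled):
        s, lab = labelled
        design = build_glm_design(s, lab, "main")
        arr = s.arrays()
        # find the design row for a trial whose previous token was blue
        trial_of_row = np.flatnonzero(
            (np.r_[False, arr.choice[:-1] >= 0])
            & (lab["ol_consistent"].to_numpy() >= 0) & (arr.choice >= 0))
        for i, t in enumerate(trial_of_row):
            sign = 1 if arr.choice[t - 1] == 1 else -1
            assert design["out"].iloc[i] == pytest.approx(
                sign * arr.outcome[t - 1] / 100.0)
            assert design["pa"].iloc[i] == (
                1.0 if lab["ol_consistent"].iloc[t] == 1 else -1.0)

    @pytest.mark.parametrize("scheme", ["by_ol_unc", "by_el_unc", "by_mag"])
    def test_partition_identity(self, labelled, scheme):
        s, lab = labelled
        main = build_glm_design(s, lab, "main").set_index("trial")
        split = build_glm_design(s, lab, scheme).set_index("trial")
        # the split design drops rows with an undefined stratum, so align
        assert 0 < len(split) <= len(main)
        for reg in ("out", "pa"):
            total = split[f"{reg}_low"] + split[f"{reg}_high"]
            assert np.allclose(total.to_numpy(),
                               main.loc[split.index, reg].to_numpy())
            assert ((split[f"{reg}_low"] == 0)
                    | (split[f"{reg}_high"] == 0)).all()

    def test_unknown_scheme_rejected(self, labelled):
        s, lab = labelled
        with pytest.raises(ValueError):
            build_glm_design(s, lab, "by_phase")

    def test_regressors_weakly_correlated(self, sampler):
        # measured on a mixed cohort like the study population
        cfg = TaskConfig()
        rng = np.random.default_rng(64)
        sessions = generate_cohort(
            cfg, {m: 3 for m in ("baseline", "el", "ol", "fixmix", "dynarb")},
            sampler, rng)
        designs = [build_glm_design(s, label_trials(s), "main")
                   for s in sessions]
        d = pd.concat(designs, ignore_index=True)
        r = np.corrcoef(d["out"], d["pa"])[0, 1]
        assert abs(r) < 0.4


class TestMixedGLM:
    def test_random_cohort_has_null_effects(self, sampler):
        cfg = TaskConfig()
        rng = np.random.default_rng(65)
        sessions = generate_cohort(cfg, {"random": 20}, sampler, rng)
        d = pd.concat([build_glm_design(s, label_trials(s), "main")
                       for s in sessions], ignore_index=True)
        res = fit_me_glm(d)
        for eff in ("out", "pa"):
            assert abs(res.fixed_effects[eff]) < 4 * res.fixed_se[eff] + 0.1

    def test_needs_multiple_subjects(self, labelled):
        s, lab = labelled
        with pytest.raises(ValueError):
            fit_me_glm(build_glm_design(s, lab, "main"))

    def test_random_effects_follow_fixed_effects(self, sampler):
        cfg = TaskConfig()
        rng = np.random.default_rng(66)
        sessions = generate_cohort(cfg, {"el": 10}, sampler, rng)
        d = pd.concat([build_glm_design(s, label_trials(s), "main")
                       for s in sessions], ignore_index=True)
        res = fit_me_glm(d)
        assert set(res.random_effects.index) == {s.subject_id
                                                for s in sessions}
        assert res.random_effects["out"].mean() == pytest.approx(
            res.fixed_effects["out"], abs=1.0)


class TestArbitrationIndex:
    def test_perfect_arbitrator_scores_one(self):
        cfg = TaskConfig()
        base = generate_session(cfg, agent="random",
                                rng=np.random.default_rng(67), list_index=7)
        df = base.trials.copy()
        for t in range(len(df)):
            lab = label_trials(Session(df))
            row = lab.iloc[t]
            in_ol_cell = (row["ol_unc"] == 0 and row["el_unc"] == 1
                          and row["magnitude"] == 0)
            in_el_cell = (row["ol_unc"] == 1 and row["el_unc"] == 0
                          and row["magnitude"] == 1)
            if in_ol_cell and row["ol_consistent"] >= 0:
                df.loc[df.index[t], "choice"] = (
                    "orange" if row["ol_consistent"] else "blue")
            elif in_el_cell and row["el_consistent"] >= 0:
                df.loc[df.index[t], "choice"] = (
                    "orange" if row["el_consistent"] else "blue")
        s = Session(df)
        idx, diag = arbitration_index(s, label_trials(s))
        assert diag["n_ol_cell"] > 0 and diag["n_el_cell"] > 0
        assert idx == 1.0

    def test_fixed_behavior_near_zero(self):
        cfg = TaskConfig(n_blocks=16, trials_per_block=20,
                         reversal_window=(8, 13))
        s = generate_session(cfg, agent="random",
                             rng=np.random.default_rng(68))
        idx, diag = arbitration_index(s, label_trials(s))
        assert abs(idx) < 0.45  # expectation 0, small cells are noisy


class TestSignatureReport:
    def test_report_columns(self, dynarb_session, random_session):
        rep = signature_report([dynarb_session, random_session])
        assert len(rep) == 2
        assert {"ol_propensity", "arbitration_index", "curve_1",
                "curve_8"} <= set(rep.columns)
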