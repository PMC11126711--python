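"""Model-agnostic behavioral signatures.

Trial-consistency classification (which token an experiential vs an
observational learner would pick given the recent history), causal
uncertainty and magnitude trial labels, choice propensities, post-reversal
learning curves, mixed-effects logistic choice regressions, and the
behavioral arbitration index.

All labels are functions of past trials only, so relabeling a truncated
session leaves earlier labels unchanged.  Labels that require the partner's
previous box are reset at block boundaries because each block introduces a
new fractal pair.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .session import Session

logger = logging.getLogger(__name__)

__all__ = [
    "label_trials", "ol_choice_propensity", "learning_curve",
    "build_glm_design", "fit_me_glm", "MixedGLMResult",
    "arbitration_index", "signature_report",
]

GLM_SCHEMES = ("main", "by_ol_unc", "by_el_unc", "by_mag")


def label_trials(session: Session,
                 magnitude_threshold: int = 25) -> pd.DataFrame:
    """Per-trial strategy-consistency and uncertainty labels.

    Columns (value -1 where history is insufficient):

    - ``el_consistent``: token (1=orange, 0=blue) an experiential learner
      would choose -- the previously rewarded token, or the other token if
      the previous choice went unrewarded.
    - ``ol_consistent``: token an observational learner would infer as the
      partner's goal -- the token the partner previously obtained if the
      partner repeated its box, the other token if it switched.
    - ``ol_unc``: 0=low / 1=high; low iff the past two observed box-token
      pairs imply the same box-to-token mapping.
    - ``el_unc``: 0=low / 1=high; low iff the past outcome-action-outcome
      triplet is win-stay-win, win-shift-loss, loss-stay-loss or
      loss-shift-win.
    - ``magnitude``: 0=low / 1=high; high iff the previous outcome exceeds
      the threshold (25 points).
    """
    arr = session.arrays()
    n = arr.n_trials
    el_cons = np.full(n, -1, dtype=np.int64)
    ol_cons = np.full(n, -1, dtype=np.int64)
    ol_unc = np.full(n, -1, dtype=np.int64)
    el_unc = np.full(n, -1, dtype=np.int64)
    mag = np.full(n, -1, dtype=np.int64)

    tib = np.zeros(n, dtype=np.int64)  # trial index within block
    for t in range(1, n):
        tib[t] = 0 if arr.block_start[t] else tib[t - 1] + 1

    for t in range(n):
        # experiential history spans blocks (tokens persist)
        if t >= 1 and arr.choice[t - 1] >= 0:
            prev = arr.choice[t - 1]
            el_cons[t] = prev if arr.rewarded[t - 1] else 1 - prev
            mag[t] = int(arr.outcome[t - 1] > magnitude_threshold)
        # observational history resets with each new fractal pair
        if tib[t] >= 1:
            same_box = arr.partner_box[t] == arr.partner_box[t - 1]
            tok = arr.observed_token[t - 1]
            ol_cons[t] = tok if same_box else 1 - tok
        if tib[t] >= 2:
            same_box = arr.partner_box[t - 1] == arr.partner_box[t - 2]
            same_tok = arr.observed_token[t - 1] == arr.observed_token[t - 2]
            ol_unc[t] = int(same_box != same_tok)
        if (t >= 2 and arr.choice[t - 1] >= 0 and arr.choice[t - 2] >= 0):
            w2, w1 = arr.rewarded[t - 2], arr.rewarded[t - 1]
            stay = arr.choice[t - 1] == arr.choice[t - 2]
            consistent = bool(w1) == (bool(w2) == stay)
            el_unc[t] = int(not consistent)
    return pd.DataFrame({
        "el_consistent": el_cons, "ol_consistent": ol_cons,
        "ol_unc": ol_unc, "el_unc": el_unc, "magnitude": mag,
    })


def ol_choice_propensity(session: Session, labels: pd.DataFrame,
                         mask: Optional[np.ndarray] = None):
    """Proportion of OL-consistent choices among EL/OL-divergent trials.

    Returns ``(propensity, n_trials)``; the propensity is NaN when no trial
    qualifies.
    """
    arr = session.arrays()
    el = labels["el_consistent"].to_numpy()
    ol = labels["ol_consistent"].to_numpy()
    use = (el >= 0) & (ol >= 0) & (el != ol) & (arr.choice >= 0)
    if mask is not None:
        use &= np.asarray(mask, bool)
    n = int(use.sum())
    if n == 0:
        return float("nan"), 0
    return float(np.mean(arr.choice[use] == ol[use])), n


def learning_curve(session: Session, n_points: int = 8,
                   include_block_starts: bool = True) -> np.ndarray:
    """Mean accuracy at post-reversal positions 1..n_points.

    Accuracy is choosing the currently more-rewarded token (scheduled
    reward probability > 0.5).  Reversal events are the within-block flips
    plus, by default, the forced flips at block boundaries; positions
    falling beyond the event's block are skipped.
    """
    arr = session.arrays()
    flips = np.flatnonzero(np.r_[False,
                                 arr.valuable_orange[1:]
                                 != arr.valuable_orange[:-1]])
    if not include_block_starts:
        flips = flips[~arr.block_start[flips]]
    if len(flips) == 0:
        raise ValueError("session contains no reversal events")
    acc = np.zeros(n_points)
    cnt = np.zeros(n_points)
    for t0 in flips:
        for p in range(n_points):
            t = t0 + p
            if t >= arr.n_trials or arr.block[t] != arr.block[t0]:
                break
            if arr.choice[t] < 0:
                continue
            acc[p] += arr.choice[t] == arr.valuable_orange[t]
            cnt[p] += 1
    with np.errstate(invalid="ignore"):
        return acc / np.where(cnt > 0, cnt, np.nan)


def build_glm_design(session: Session, labels: pd.DataFrame,
                     scheme: str = "main",
                     scale_outcome: bool = True) -> pd.DataFrame:
    """Design rows for the mixed-effects choice regression.

    ``out`` is the previous trial's outcome, signed by the previously
    chosen token (+ for orange) and scaled to [-1, 1] by default;``pa`` is
    +/-1 by whether the partner's current action implies an orange or blue
    goal.  Split schemes zero each regressor outside its uncertainty or
    magnitude stratum, so the low and high columns partition the main
    regressor.  Rows with undefined regressors (or a missing choice) are
    dropped, never imputed.
    """
    if scheme not in GLM_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; one of {GLM_SCHEMES}")
    arr = session.arrays()
    n = arr.n_trials
    scale = 100.0 if scale_outcome else 1.0
    prev_ok = np.r_[False, arr.choice[:-1] >= 0]
    prev_sign = np.r_[0, np.where(arr.choice[:-1] == 1, 1, -1)]
    out = np.r_[0.0, arr.outcome[:-1]] / scale * prev_sign
    ol = labels["ol_consistent"].to_numpy()
    pa = np.where(ol == 1, 1.0, -1.0)
    keep = prev_ok & (ol >= 0) & (arr.choice >= 0)
    df = pd.DataFrame({
        "trial": np.arange(n), "choice": arr.choice, "out": out, "pa": pa,
        "sub": session.subject_id,
    })
    if scheme != "main":
        col = {"by_ol_unc": "ol_unc", "by_el_unc": "el_unc",
               "by_mag": "magnitude"}[scheme]
        strat = labels[col].to_numpy()
        keep &= strat >= 0
        for reg in ("out", "pa"):
            df[f"{reg}_low"] = df[reg] * (strat == 0)
            df[f"{reg}_high"] = df[reg] * (strat == 1)
        df = df.drop(columns=["out", "pa"])
    return df[keep].reset_index(drop=True)


@dataclass
class MixedGLMResult:
    """Mixed-effects logistic regression summary."""

    fixed_effects: pd.Series
    fixed_se: pd.Series
    random_effects: pd.DataFrame   # per-subject total (fixed + deviation)
    method: str                    # "vb" or "two_stage"
    converged: bool


def _two_stage_glm(design: pd.DataFrame, predictors) -> MixedGLMResult:
    """Per-subject ridge-logistic fits summarized across subjects."""
    import statsmodels.api as sm

    coefs = {}
    for sub, d in design.groupby("sub"):
        X = sm.add_constant(d[predictors].to_numpy(), has_constant="add")
        mod = sm.GLM(d["choice"].to_numpy(), X,
                     family=sm.families.Binomial())
        try:
            res = mod.fit_regularized(alpha=0.02, L1_wt=0.0)
            coefs[sub] = res.params
        except Exception:  # pragma: no cover
            logger.warning("per-subject GLM failed for %s", sub)
    cf = pd.DataFrame(coefs, index=["intercept", *predictors]).T
    fe = cf.mean(axis=0)
    se = cf.std(axis=0, ddof=1) / np.sqrt(len(cf))
    return MixedGLMResult(fixed_effects=fe, fixed_se=se, random_effects=cf,
                          method="two_stage", converged=True)


def fit_me_glm(design: pd.DataFrame,
               n_subjects_min: int = 2) -> MixedGLMResult:
    """Mixed-effects logistic regression of choice on the design columns.

    Random intercept and random slopes by subject, fitted by variational
    Bayes (statsmodels ``BinomialBayesMixedGLM``).  If the variational fit
    fails, falls back to per-subject ridge-logistic fits summarized across
    subjects (flagged in ``method``).
    """
    if design["sub"].nunique() < n_subjects_min:
        raise ValueError(f"need >= {n_subjects_min} subjects")
    predictors = [c for c in design.columns
                  if c not in ("choice", "sub", "trial")]
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    formula = "choice ~ " + " + ".join(predictors)
    vc_formulas = {"icept": "0 + C(sub)"}
    vc_formulas.update({p: f"0 + C(sub):{p}" for p in predictors})
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = BinomialBayesMixedGLM.from_formula(
                formula, vc_formulas, design, vcp_p=2.0, fe_p=2.5)
            fit = model.fit_vb()
        # quasi-separated cohorts (near-deterministic choices) blow up the
        # variational posterior; treat that as a convergence failure
        if (not getattr(fit, "converged", True)
                or not np.all(np.isfinite(fit.fe_mean))
                or np.abs(fit.vc_mean).max() > 25.0):
            raise RuntimeError("variational posterior diverged")
        fe_names = ["intercept", *predictors]
        fe = pd.Series(fit.fe_mean, index=fe_names)
        se = pd.Series(fit.fe_sd, index=fe_names)
        # per-subject totals: fixed effect + that subject's deviation
        subs = sorted(design["sub"].unique())
        vc = pd.Series(fit.vc_mean, index=model.vc_names)
        re = pd.DataFrame(index=subs, columns=fe_names, dtype=float)
        for sub in subs:
            re.loc[sub, "intercept"] = fe["intercept"] + vc.get(
                f"C(sub)[{sub}]", 0.0)
            for p in predictors:
                re.loc[sub, p] = fe[p] + vc.get(f"C(sub)[{sub}]:{p}", 0.0)
        return MixedGLMResult(fixed_effects=fe, fixed_se=se,
                              random_effects=re, method="vb", converged=True)
    except Exception as err:
        logger.warning("variational mixed GLM failed (%s); falling back to "
                       "two-stage per-subject fits", err)
        return _two_stage_glm(design, predictors)


def arbitration_index(session: Session, labels: pd.DataFrame):
    """Difference in OL choice propensity between the cell maximally
    favoring OL (low OL uncertainty, high EL uncertainty, low magnitude)
    and the cell maximally favoring EL (the reverse).

    Returns ``(index, diagnostics)``; the index is NaN when either cell is
    empty.
    """
    ol = labels["ol_unc"].to_numpy()
    el = labels["el_unc"].to_numpy()
    mag = labels["magnitude"].to_numpy()
    cell_ol = (ol == 0) & (el == 1) & (mag == 0)
    cell_el = (ol == 1) & (el == 0) & (mag == 1)
    p_ol, n_ol = ol_choice_propensity(session, labels, mask=cell_ol)
    p_el, n_el = ol_choice_propensity(session, labels, mask=cell_el)
    diag = {"n_ol_cell": n_ol, "n_el_cell": n_el,
            "prop_ol_cell": p_ol, "prop_el_cell": p_el}
    if n_ol == 0 or n_el == 0:
        return float("nan"), diag
    return p_ol - p_el, diag


def signature_report(sessions: Sequence[Session],
                     n_curve_points: int = 8) -> pd.DataFrame:
    """Per-subject battery: learning curve, propensities, arbitration index.

    One row per subject; GLM effects are fitted cohort-wise and are not
    included here (see :func:`fit_me_glm`).
    """
    rows = []
    for s in sessions:
        labels = label_trials(s)
        prop, n_prop = ol_choice_propensity(s, labels)
        curve = learning_curve(s, n_points=n_curve_points)
        arb, diag = arbitration_index(s, labels)
        row = {"subject_id": s.subject_id, "true_model": s.true_model,
               "ol_propensity": prop, "n_divergent": n_prop,
               "arbitration_index": arb, **diag}
        row.update({f"curve_{i + 1}": c for i, c in enumerate(curve)})
        rows.append(row)
    return pd.DataFrame(rows)
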