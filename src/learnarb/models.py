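"""The five trial-by-trial strategy models.

Experiential learning (EL) tracks each token's reward probability with a
delta rule and boosts choice by recent reward magnitudes; observational
learning (OL) infers the partner's goal token by learning box-to-token
transition probabilities from the partner's choices; the fixed mixture
blends the two experts with a constant weight; dynamic arbitration weights
them trial-by-trial by their relative reliability (normalized unsigned
prediction errors, plus outcome magnitude for EL); and the baseline model
captures non-learning heuristics (color, side, sticky and imitation biases).

Every model exposes the same incremental interface (``initial_state`` /
``observe`` / ``prob_orange`` / ``learn``) used for simulation and latent
traces; likelihood evaluation additionally has a fast path through
:mod:`learnarb._cores` (verified equivalent to the incremental path in the
test suite).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import _cores
from .session import Session, SessionArrays

__all__ = [
    "NormalizationPolicy", "ModelSpec", "MODELS", "get_model",
    "el_step", "el_choice_prob", "ol_step", "ol_choice_prob",
    "reliability_ol", "reliability_el", "arbitration_weight",
    "combined_choice_prob", "baseline_choice_prob",
    "model_nll", "trace_nll", "simulate_choices",
]

_PMIN = 1e-12

TRACE_COLUMNS = [
    "TokV_exp_or", "TokV_exp_bl", "M_or", "M_bl", "eRPE",
    "ActV_obs_A", "ActV_obs_B", "oSPE", "TokV_obs_or", "TokV_obs_bl",
    "R_OL", "R_EL", "omega_t", "P_exp_or", "P_obs_or", "P_or",
]


def _logistic(z: float) -> float:
    return 1.0 / (1.0 + math.exp(-min(35.0, max(-35.0, z))))


# ---------------------------------------------------------------------------
# elementary model operations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizationPolicy:
    """Min-max bounds for the unsigned prediction errors feeding reliability.

    Both prediction errors are differences of probabilities/indicators, so
    their theoretical range is [0, 1]; these causal bounds are the default.
    Empirical whole-session bounds can be supplied instead (post hoc, not
    usable during generation).  Degenerate bounds (max == min) fall back to
    reliability 0 with a warning.
    """

    ospe_bounds: Tuple[float, float] = (0.0, 1.0)
    erpe_bounds: Tuple[float, float] = (0.0, 1.0)

    @staticmethod
    def _norm(x: float, bounds: Tuple[float, float]) -> Optional[float]:
        lo, hi = bounds
        if hi == lo:
            warnings.warn("degenerate min-max bounds; reliability set to 0")
            return None
        return (x - lo) / (hi - lo)


THEORETICAL = NormalizationPolicy()


def el_step(tokv_orange: float, m_or: float, m_bl: float, choice: int,
            rewarded: bool, outcome_points: float, alpha_exp: float):
    """Experiential delta-rule update after the participant's outcome.

    Returns ``(tokv_orange, m_or, m_bl, eRPE)``.  The chosen token's value
    moves toward the reward indicator; the unchosen value is the complement
    (token reward probabilities sum to 1).  The magnitude tracker of a
    rewarded chosen token is set to the outcome; any other tracker decays
    by 50%.
    """
    r = 1.0 if rewarded else 0.0
    if choice == 1:
        erpe = r - tokv_orange
        tokv_orange = tokv_orange + alpha_exp * erpe
        m_or = float(outcome_points) if rewarded else 0.5 * m_or
        m_bl = 0.5 * m_bl
    else:
        v_bl = 1.0 - tokv_orange
        erpe = r - v_bl
        tokv_orange = 1.0 - (v_bl + alpha_exp * erpe)
        m_bl = float(outcome_points) if rewarded else 0.5 * m_bl
        m_or = 0.5 * m_or
    return tokv_orange, m_or, m_bl, erpe


def el_choice_prob(tokv_orange: float, m_or: float, m_bl: float,
                   beta_exp: float, mu: float) -> float:
    """Softmax of the token value difference plus the magnitude boost."""
    return _logistic(beta_exp * (2.0 * tokv_orange - 1.0) + mu * (m_or - m_bl))


def ol_step(actv_a: float, actv_b: float, partner_box: int,
            observed_token: int, alpha_obs: float):
    """Observational update of the box-to-token transition probabilities.

    Returns ``(actv_a, actv_b, oSPE, tokv_obs_orange)``.  The chosen box's
    orange-probability moves toward the observed token indicator; the
    unchosen box receives the opposite (counterfactual) update, clipped to
    [0, 1].  The partner's inferred goal gives the orange token a value
    equal to the chosen box's (updated) orange-probability.
    """
    if partner_box == 0:
        ospe = observed_token - actv_a
        actv_a += alpha_obs * ospe
        actv_b -= alpha_obs * ospe
    else:
        ospe = observed_token - actv_b
        actv_b += alpha_obs * ospe
        actv_a -= alpha_obs * ospe
    actv_a = min(1.0, max(0.0, actv_a))
    actv_b = min(1.0, max(0.0, actv_b))
    tokv_obs_or = actv_a if partner_box == 0 else actv_b
    return actv_a, actv_b, ospe, tokv_obs_or


def ol_choice_prob(tokv_obs_orange: float, beta_obs: float) -> float:
    """Softmax of the inferred-goal token value difference."""
    return _logistic(beta_obs * (2.0 * tokv_obs_orange - 1.0))


def reliability_ol(ospe: float,
                   norm: NormalizationPolicy = THEORETICAL) -> float:
    """OL reliability in [-1, 1]: +1 at minimal surprise, -1 at maximal."""
    z = norm._norm(abs(ospe), norm.ospe_bounds)
    if z is None:
        return 0.0
    return -(2.0 * z - 1.0)


def reliability_el(erpe_prev: float, outcome_prev: float,
                   norm: NormalizationPolicy = THEORETICAL) -> float:
    """EL reliability in [-1, 1] from the previous trial's prediction error
    and scaled outcome magnitude."""
    z = norm._norm(abs(erpe_prev), norm.erpe_bounds)
    if z is None:
        return 0.0 + outcome_prev / 100.0
    return -z + outcome_prev / 100.0


def arbitration_weight(r_ol: float, r_el: float, delta: float) -> float:
    """Softmax of the reliability difference plus the OL-over-EL bias."""
    return _logistic(r_ol - r_el + delta)


def combined_choice_prob(p_obs: float, p_exp: float, omega: float) -> float:
    """Mixture-of-experts choice probability."""
    return omega * p_obs + (1.0 - omega) * p_exp


def baseline_choice_prob(orange_left: int, own_prev_side: Optional[int],
                         partner_left: int, b_color: float, b_side: float,
                         b_sticky: float, b_imit: float) -> float:
    """Additive-logistic combination of four non-learning biases."""
    s = 1.0 if orange_left == 1 else -1.0
    if own_prev_side is None:
        rep = 0.0
    else:
        rep = 1.0 if orange_left == own_prev_side else -1.0
    imi = 1.0 if orange_left == partner_left else -1.0
    return _logistic(b_color + b_side * s + b_sticky * rep + b_imit * imi)


# ---------------------------------------------------------------------------
# model specifications
# ---------------------------------------------------------------------------

_TRANSFORMS = {
    "sigmoid": (lambda x: 1.0 / (1.0 + np.exp(-np.clip(x, -35, 35))),
                lambda a: float(np.log(a / (1.0 - a)))),
    "exp": (lambda x: float(np.exp(np.clip(x, -35, 35))),
            lambda a: float(np.log(a))),
    "identity": (lambda x: float(x), lambda a: float(a)),
}


class ModelSpec:
    """A strategy model: named parameters, transforms and trial dynamics.

    Learning rates and mixture weights live on the unit interval (sigmoid
    transform), inverse temperatures on the positive half-line (exp), and
    biases on the reals (identity); MAP fitting operates in the
    unconstrained image.
    """

    name: str
    param_info: List[Tuple[str, str]]

    def __init__(self, name, param_info, kind):
        self.name = name
        self.param_info = param_info
        self.kind = kind  # _cores kind code, or None for baseline

    @property
    def k(self) -> int:
        return len(self.param_info)

    @property
    def param_names(self) -> List[str]:
        return [p for p, _ in self.param_info]

    def to_constrained(self, x) -> Dict[str, float]:
        return {p: _TRANSFORMS[tr][0](xi)
                for (p, tr), xi in zip(self.param_info, np.asarray(x, float))}

    def to_unconstrained(self, params: Dict[str, float]) -> np.ndarray:
        return np.array([_TRANSFORMS[tr][1](params[p])
                         for p, tr in self.param_info])

    # --- incremental interface -------------------------------------------
    def initial_state(self) -> dict:
        return {
            "tokv_or": 0.5, "m_or": 0.0, "m_bl": 0.0,
            "actv_a": 0.5, "actv_b": 0.5,
            "ospe": 0.0, "tokv_obs_or": 0.5,
            "erpe": np.nan, "erpe_prev": 0.0, "outcome_prev": 0.0,
            "prev_side": None,
            "r_ol": np.nan, "r_el": np.nan, "omega_t": np.nan,
            "p_exp": np.nan, "p_obs": np.nan,
        }

    def observe(self, state: dict, ctx: dict, params: Dict[str, float],
                norm: NormalizationPolicy = THEORETICAL) -> None:
        """Pre-choice phase: watch the partner, update transition beliefs."""
        if ctx["block_start"]:
            state["actv_a"] = state["actv_b"] = 0.5  # new fractal pair
        if self.name == "baseline":
            return
        alpha_obs = params.get("alpha_obs", 0.0)
        (state["actv_a"], state["actv_b"], state["ospe"],
         state["tokv_obs_or"]) = ol_step(
            state["actv_a"], state["actv_b"], ctx["partner_box"],
            ctx["observed_token"], alpha_obs)
        if self.name == "dynarb":
            state["r_ol"] = reliability_ol(state["ospe"], norm)
            state["r_el"] = reliability_el(state["erpe_prev"],
                                           state["outcome_prev"], norm)

    def prob_orange(self, state: dict, ctx: dict,
                    params: Dict[str, float]) -> float:
        if self.name == "baseline":
            return baseline_choice_prob(
                ctx["orange_left"], state["prev_side"], ctx["partner_left"],
                params["b_color"], params["b_side"], params["b_sticky"],
                params["b_imit"])
        p_exp = el_choice_prob(state["tokv_or"], state["m_or"], state["m_bl"],
                               params.get("beta_exp", 0.0),
                               params.get("mu", 0.0))
        p_obs = ol_choice_prob(state["tokv_obs_or"],
                               params.get("beta_obs", 0.0))
        state["p_exp"], state["p_obs"] = p_exp, p_obs
        if self.name == "el":
            return p_exp
        if self.name == "ol":
            return p_obs
        if self.name == "fixmix":
            state["omega_t"] = params["omega"]
        else:  # dynarb
            state["omega_t"] = arbitration_weight(
                state["r_ol"], state["r_el"], params["delta"])
        return combined_choice_prob(p_obs, p_exp, state["omega_t"])

    def learn(self, state: dict, ctx: dict, choice: int, rewarded: int,
              outcome: float, params: Dict[str, float]) -> None:
        """Post-outcome phase.  A missed choice carries the state forward
        (no experienced outcome), and invalidates the own-side history."""
        if choice < 0:
            state["prev_side"] = None
            state["erpe"] = np.nan
            return
        state["prev_side"] = (ctx["orange_left"] if choice == 1
                              else 1 - ctx["orange_left"])
        if self.name == "baseline":
            return
        (state["tokv_or"], state["m_or"], state["m_bl"],
         state["erpe"]) = el_step(
            state["tokv_or"], state["m_or"], state["m_bl"], choice,
            bool(rewarded), outcome, params.get("alpha_exp", 0.0))
        state["erpe_prev"] = state["erpe"]
        state["outcome_prev"] = float(outcome)


MODELS: Dict[str, ModelSpec] = {
    "baseline": ModelSpec("baseline", [("b_color", "identity"),
                                       ("b_side", "identity"),
                                       ("b_sticky", "identity"),
                                       ("b_imit", "identity")], None),
    "el": ModelSpec("el", [("alpha_exp", "sigmoid"),
                           ("beta_exp", "exp"),
                           ("mu", "identity")], _cores.KIND_EL),
    "ol": ModelSpec("ol", [("alpha_obs", "sigmoid"),
                           ("beta_obs", "exp")], _cores.KIND_OL),
    "fixmix": ModelSpec("fixmix", [("alpha_exp", "sigmoid"),
                                   ("beta_exp", "exp"),
                                   ("mu", "identity"),
                                   ("alpha_obs", "sigmoid"),
                                   ("beta_obs", "exp"),
                                   ("omega", "sigmoid")], _cores.KIND_FIXMIX),
    "dynarb": ModelSpec("dynarb", [("alpha_exp", "sigmoid"),
                                   ("beta_exp", "exp"),
                                   ("mu", "identity"),
                                   ("alpha_obs", "sigmoid"),
                                   ("beta_obs", "exp"),
                                   ("delta", "identity")], _cores.KIND_DYNARB),
}

MODEL_ORDER = ["baseline", "el", "ol", "fixmix", "dynarb"]

#: display names used in reports
MODEL_LABELS = {
    "baseline": "Baseline", "el": "ExpLearn", "ol": "ObsLearn",
    "fixmix": "FixArb", "dynarb": "DynArb",
}


def get_model(name: str) -> ModelSpec:
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; choose from {MODEL_ORDER}")


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _prob_trace_fast(model: ModelSpec, arr: SessionArrays,
                     params: Dict[str, float]) -> np.ndarray:
    p = np.empty(arr.n_trials)
    if model.name == "baseline":
        _cores.baseline_kernel(
            params["b_color"], params["b_side"], params["b_sticky"],
            params["b_imit"], arr.orange_left, arr.partner_left,
            arr.choice, p)
    else:
        _cores.learning_kernel(
            model.kind,
            params.get("alpha_exp", 0.0), params.get("beta_exp", 0.0),
            params.get("mu", 0.0), params.get("alpha_obs", 0.0),
            params.get("beta_obs", 0.0), params.get("omega", 0.0),
            params.get("delta", 0.0),
            arr.block_start.astype(np.int64), arr.partner_box,
            arr.observed_token, arr.choice, arr.rewarded,
            arr.outcome.astype(np.float64), p)
    return p


def _prob_trace_incremental(model: ModelSpec, arr: SessionArrays,
                            params: Dict[str, float],
                            norm: NormalizationPolicy = THEORETICAL):
    p = np.empty(arr.n_trials)
    rows = []
    state = model.initial_state()
    for t in range(arr.n_trials):
        ctx = {
            "block_start": bool(arr.block_start[t]),
            "partner_box": int(arr.partner_box[t]),
            "observed_token": int(arr.observed_token[t]),
            "orange_left": int(arr.orange_left[t]),
            "partner_left": int(arr.partner_left[t]),
        }
        model.observe(state, ctx, params, norm)
        p[t] = model.prob_orange(state, ctx, params)
        model.learn(state, ctx, int(arr.choice[t]), int(arr.rewarded[t]),
                    float(arr.outcome[t]), params)
        rows.append({
            "TokV_exp_or": state["tokv_or"],
            "TokV_exp_bl": 1.0 - state["tokv_or"],
            "M_or": state["m_or"], "M_bl": state["m_bl"],
            "eRPE": state["erpe"],
            "ActV_obs_A": state["actv_a"], "ActV_obs_B": state["actv_b"],
            "oSPE": state["ospe"],
            "TokV_obs_or": state["tokv_obs_or"],
            "TokV_obs_bl": 1.0 - state["tokv_obs_or"],
            "R_OL": state["r_ol"], "R_EL": state["r_el"],
            "omega_t": state["omega_t"],
            "P_exp_or": state["p_exp"], "P_obs_or": state["p_obs"],
            "P_or": p[t],
        })
    return p, pd.DataFrame(rows, columns=TRACE_COLUMNS)


def _nll_from_probs(p: np.ndarray, choice: np.ndarray,
                    mask: Optional[np.ndarray]) -> float:
    use = choice >= 0
    if mask is not None:
        use = use & mask
    pc = np.where(choice == 1, p, 1.0 - p)[use]
    if np.any(~np.isfinite(pc)):
        t = int(np.flatnonzero(use)[np.argmax(~np.isfinite(pc))])
        raise FloatingPointError(f"non-finite choice probability at trial {t}")
    return float(-np.sum(np.log(np.clip(pc, _PMIN, 1.0))))


def model_nll(session: Session, model, params: Dict[str, float],
              mask: Optional[np.ndarray] = None,
              return_probs: bool = False):
    """Total negative log likelihood of the observed choices under a model.

    ``mask`` (boolean per trial) restricts the trials that are *scored*;
    latent updates always run over the full sequence (the observation phase
    of every trial is seen regardless of whether the choice is scored).
    """
    if isinstance(model, str):
        model = get_model(model)
    arr = session.arrays() if isinstance(session, Session) else session
    p = _prob_trace_fast(model, arr, params)
    nll = _nll_from_probs(p, arr.choice, mask)
    if return_probs:
        return nll, p
    return nll


def trace_nll(session: Session, model, params: Dict[str, float],
              mask: Optional[np.ndarray] = None,
              norm: NormalizationPolicy = THEORETICAL):
    """Like :func:`model_nll` but via the incremental path, returning the
    full latent trace (one row per trial)."""
    if isinstance(model, str):
        model = get_model(model)
    arr = session.arrays() if isinstance(session, Session) else session
    p, trace = _prob_trace_incremental(model, arr, params, norm)
    return _nll_from_probs(p, arr.choice, mask), trace


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_choices(session: Session, model, params: Dict[str, float],
                     rng: np.random.Generator) -> Session:
    """Replay a session's partner stream with model-generated choices.

    The schedule and the partner's observed behavior are retained; the
    participant's choices are sampled from the model's per-trial P(orange)
    and outcomes are re-sampled for the newly chosen tokens under the
    scheduled reward probabilities (magnitudes uniform over the block's
    regime range).
    """
    if isinstance(model, str):
        model = get_model(model)
    arr = session.arrays()
    regime = session.trials["mag_regime"].to_numpy()
    n = arr.n_trials
    choices = np.empty(n, dtype=np.int64)
    rewarded = np.empty(n, dtype=np.int64)
    outcomes = np.empty(n, dtype=np.int64)
    state = model.initial_state()
    for t in range(n):
        ctx = {
            "block_start": bool(arr.block_start[t]),
            "partner_box": int(arr.partner_box[t]),
            "observed_token": int(arr.observed_token[t]),
            "orange_left": int(arr.orange_left[t]),
            "partner_left": int(arr.partner_left[t]),
        }
        model.observe(state, ctx, params)
        p_or = model.prob_orange(state, ctx, params)
        c = int(rng.random() < p_or)
        p_rew = (arr.rew_prob_orange[t] if c == 1
                 else 1.0 - arr.rew_prob_orange[t])
        r = int(rng.random() < p_rew)
        if r:
            lo, hi = (45, 55) if regime[t] == "narrow" else (1, 99)
            pts = int(rng.integers(lo, hi + 1))
        else:
            pts = 0
        model.learn(state, ctx, c, r, float(pts), params)
        choices[t], rewarded[t], outcomes[t] = c, r, pts
    out = session.copy_with_choices(choices, rewarded, outcomes)
    out.true_model = model.name
    out.true_params = dict(params)
    return out
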