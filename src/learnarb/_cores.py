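"""Fast per-trial choice-probability kernels.

One straight-line loop covers the four learning models (experiential-only,
observational-only, fixed mixture, dynamic arbitration) and one covers the
baseline-heuristics model.  The kernels fill a per-trial P(orange) array;
likelihood assembly, masking and traces live in :mod:`learnarb.models`.
They are written in nopython-compatible style and JIT-compiled with numba
when it is importable; the pure-Python fallback is the same code object.
"""

from __future__ import annotations

import math

# model kind codes for the learning-family kernel
KIND_EL = 0
KIND_OL = 1
KIND_FIXMIX = 2
KIND_DYNARB = 3


def _logistic(z: float) -> float:
    if z > 35.0:
        z = 35.0
    elif z < -35.0:
        z = -35.0
    return 1.0 / (1.0 + math.exp(-z))


def learning_kernel(kind, alpha_exp, beta_exp, mu, alpha_obs, beta_obs,
                    omega, delta, block_start, partner_box, observed_token,
                    choice, rewarded, outcome, p):
    """Fill ``p`` with P(orange) per trial for the learning-model family.

    Timing within a trial: observe the partner (observational update with
    the current trial's box-token pair), compute choice probability, then
    apply the experiential update from the participant's own outcome.
    Reliabilities use theoretical [0, 1] prediction-error bounds.
    """
    v = 0.5            # experiential P(orange token rewarded)
    m_or = 0.0         # magnitude trackers
    m_bl = 0.0
    actv_a = 0.5       # P(box A -> orange), P(box B -> orange)
    actv_b = 0.5
    erpe_prev = 0.0
    out_prev = 0.0
    n = len(choice)
    for t in range(n):
        if block_start[t]:
            actv_a = 0.5
            actv_b = 0.5
        # --- observational update (precedes the participant's choice)
        if partner_box[t] == 0:
            ospe = observed_token[t] - actv_a
            actv_a += alpha_obs * ospe
            actv_b -= alpha_obs * ospe
        else:
            ospe = observed_token[t] - actv_b
            actv_b += alpha_obs * ospe
            actv_a -= alpha_obs * ospe
        if actv_a < 0.0:
            actv_a = 0.0
        elif actv_a > 1.0:
            actv_a = 1.0
        if actv_b < 0.0:
            actv_b = 0.0
        elif actv_b > 1.0:
            actv_b = 1.0
        tokv_obs_or = actv_a if partner_box[t] == 0 else actv_b
        # --- choice probabilities
        p_obs = _logistic(beta_obs * (2.0 * tokv_obs_or - 1.0))
        p_exp = _logistic(beta_exp * (2.0 * v - 1.0) + mu * (m_or - m_bl))
        if kind == 0:
            pt = p_exp
        elif kind == 1:
            pt = p_obs
        elif kind == 2:
            pt = omega * p_obs + (1.0 - omega) * p_exp
        else:
            r_ol = 1.0 - 2.0 * abs(ospe)
            r_el = -abs(erpe_prev) + out_prev / 100.0
            w = _logistic(r_ol - r_el + delta)
            pt = w * p_obs + (1.0 - w) * p_exp
        p[t] = pt
        # --- experiential update from the participant's own outcome
        c = choice[t]
        if c >= 0:
            r = rewarded[t]
            if c == 1:
                erpe = r - v
                v += alpha_exp * erpe
                if r == 1:
                    m_or = outcome[t]
                else:
                    m_or *= 0.5
                m_bl *= 0.5
            else:
                v_bl = 1.0 - v
                erpe = r - v_bl
                v_bl += alpha_exp * erpe
                v = 1.0 - v_bl
                if r == 1:
                    m_bl = outcome[t]
                else:
                    m_bl *= 0.5
                m_or *= 0.5
            erpe_prev = erpe
            out_prev = outcome[t]


def baseline_kernel(b_color, b_side, b_sticky, b_imit,
                    orange_left, partner_left, choice, p):
    """Fill ``p`` for the baseline-heuristics model.

    Four additive biases on the logit of choosing orange: color, left side,
    repeating one's own last side, imitating the partner's displayed side.
    """
    prev_side = -1  # own last left/right action; -1 = undefined
    n = len(choice)
    for t in range(n):
        s = 1.0 if orange_left[t] == 1 else -1.0
        if prev_side < 0:
            rep = 0.0
        elif orange_left[t] == prev_side:
            rep = 1.0
        else:
            rep = -1.0
        imi = 1.0 if orange_left[t] == partner_left[t] else -1.0
        p[t] = _logistic(b_color + b_side * s + b_sticky * rep + b_imit * imi)
        c = choice[t]
        if c >= 0:
            prev_side = orange_left[t] if c == 1 else 1 - orange_left[t]
        else:
            prev_side = -1


try:  # pragma: no cover - exercised implicitly wherever numba is present
    from numba import njit

    _logistic = njit(cache=True)(_logistic)
    learning_kernel = njit(cache=True)(learning_kernel)
    baseline_kernel = njit(cache=True)(baseline_kernel)
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False
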