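"""Independent step-by-step trace oracle for the five strategy models.

A deliberately plain re-derivation of each model's trial loop, written
spreadsheet-style over dictionaries keyed by token color, kept independent
of the package's likelihood code so it can serve as a cross-check.
"""

import math

import numpy as np


def _sm(z):
    z = max(-35.0, min(35.0, z))
    return 1.0 / (1.0 + math.exp(-z))


def oracle_probs(session, model_name, params):
    """Per-trial P(choose orange) for one session under one model."""
    df = session.trials
    n = len(df)
    probs = np.zeros(n)

    # experiential state
    tokv = {"orange": 0.5, "blue": 0.5}
    mag = {"orange": 0.0, "blue": 0.0}
    erpe_prev = 0.0
    outcome_prev = 0.0
    # observational state
    actv = {"A": 0.5, "B": 0.5}
    # baseline state
    own_prev_side = None

    other = {"orange": "blue", "blue": "orange", "A": "B", "B": "A"}

    prev_block = None
    for t in range(n):
        row = df.iloc[t]
        if row["block"] != prev_block:
            actv = {"A": 0.5, "B": 0.5}  # new fractal pair
            prev_block = row["block"]

        # ---- observation phase: partner chooses a box, token revealed
        box = row["partner_box"]
        token = row["observed_token"]
        token_is_orange = 1.0 if token == "orange" else 0.0
        ospe = token_is_orange - actv[box]
        actv[box] = actv[box] + params.get("alpha_obs", 0.0) * ospe
        actv[other[box]] = actv[other[box]] - params.get("alpha_obs", 0.0) * ospe
        for k in actv:
            actv[k] = max(0.0, min(1.0, actv[k]))
        tokv_obs = {"orange": actv[box], "blue": 1.0 - actv[box]}

        # ---- choice probability
        if model_name == "baseline":
            s = 1.0 if row["orange_side"] == "left" else -1.0
            if own_prev_side is None:
                rep = 0.0
            else:
                rep = 1.0 if row["orange_side"] == own_prev_side else -1.0
            imi = 1.0 if row["orange_side"] == row["partner_side"] else -1.0
            p = _sm(params["b_color"] + params["b_side"] * s
                    + params["b_sticky"] * rep + params["b_imit"] * imi)
        else:
            p_exp = _sm(params.get("beta_exp", 0.0)
                        * (tokv["orange"] - tokv["blue"])
                        + params.get("mu", 0.0)
                        * (mag["orange"] - mag["blue"]))
            p_obs = _sm(params.get("beta_obs", 0.0)
                        * (tokv_obs["orange"] - tokv_obs["blue"]))
            if model_name == "el":
                p = p_exp
            elif model_name == "ol":
                p = p_obs
            elif model_name == "fixmix":
                w = params["omega"]
                p = w * p_obs + (1.0 - w) * p_exp
            elif model_name == "dynarb":
                r_ol = -(2.0 * (abs(ospe) - 0.0) / (1.0 - 0.0) - 1.0)
                r_el = -(abs(erpe_prev) - 0.0) / (1.0 - 0.0) \
                    + outcome_prev / 100.0
                w = _sm(r_ol - r_el + params["delta"])
                p = w * p_obs + (1.0 - w) * p_exp
            else:
                raise ValueError(model_name)
        probs[t] = p

        # ---- learning phase: participant's own choice and outcome
        ch = row["choice"]
        if ch == "":
            own_prev_side = None
            continue
        own_prev_side = (row["orange_side"] if ch == "orange"
                         else {"left": "right", "right": "left"}[row["orange_side"]])
        if model_name == "baseline":
            continue
        reward = 1.0 if row["outcome"] > 0 else 0.0
        erpe = reward - tokv[ch]
        tokv[ch] = tokv[ch] + params.get("alpha_exp", 0.0) * erpe
        tokv[other[ch]] = 1.0 - tokv[ch]
        if reward:
            mag[ch] = float(row["outcome"])
        else:
            mag[ch] = mag[ch] / 2.0
        mag[other[ch]] = mag[other[ch]] / 2.0
        erpe_prev = erpe
        outcome_prev = float(row["outcome"])
    return probs


def oracle_nll(session, model_name, params):
    probs = oracle_probs(session, model_name, params)
    nll = 0.0
    for t, row in enumerate(session.trials.itertuples(index=False)):
        if row.choice == "orange":
            nll -= math.log(probs[t])
        elif row.choice == "blue":
            nll -= math.log(1.0 - probs[t])
    return nll
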