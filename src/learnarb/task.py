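"""Generative task design: probability schedules and the informed partner.

The task is a two-player token game.  On every trial the participant first
watches a partner choose between two boxes (new fractal pair each block) and
sees which token (orange or blue) the box delivers; the participant then
chooses a token directly and receives 0 points (no reward) or 1-99 points.
Two probability streams govern the trial: the box-to-token transition
probability (constant within a block, 80/20 or 60/40) and the token reward
probability (80/20 or 60/40, with one mid-block reversal of the valuable
token plus a forced flip at every block boundary).  Reward magnitudes are
drawn from a narrow ([45, 55]) or wide ([1, 99]) range depending on the
block's magnitude regime.

The partner is informed of the currently valuable token and learns only
which box delivers it, via a delta rule with a high learning rate and a
high-precision softmax, so its choices carry a strong observational signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .session import Session, SessionArrays, TOKENS, BOXES

__all__ = [
    "TaskConfig", "PartnerParams", "Schedule",
    "build_schedule", "simulate_partner", "generate_session",
    "generate_cohort",
]


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the generative task design.

    Defaults reproduce the deposited study conditions: 8 blocks of 20
    trials, transition and reward contingencies drawn from {0.8, 0.6},
    one within-block reversal, two reward-contingency segments per block,
    and 16 distinct trial lists.
    """

    n_blocks: int = 8
    trials_per_block: int = 20
    transition_levels: tuple = (0.8, 0.6)
    reward_levels: tuple = (0.8, 0.6)
    narrow_range: tuple = (45, 55)
    wide_range: tuple = (1, 99)
    magnitude_threshold: int = 25
    n_trial_lists: int = 16
    rng_seed: int = 2024
    #: inclusive window (0-based trial-in-block) for the within-block reversal;
    #: leaves >= 7 post-reversal trials for the learning-curve analysis
    reversal_window: tuple = (8, 13)
    #: number of equal reward-contingency segments per block
    segments_per_block: int = 2
    #: force a valuable-token flip at every block boundary
    flip_between_blocks: bool = True

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("n_blocks and trials_per_block must be >= 1")
        for p in (*self.transition_levels, *self.reward_levels):
            if not 0.0 < p < 1.0:
                raise ValueError(f"probability {p} outside (0, 1)")
        if self.n_trial_lists < 1:
            raise ValueError("n_trial_lists must be >= 1")
        if self.segments_per_block < 1:
            raise ValueError("segments_per_block must be >= 1")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass(frozen=True)
class PartnerParams:
    """Delta-rule learner that generates the partner's box choices."""

    learning_rate: float = 0.8
    inverse_temperature: float = 10.0
    #: at a token-value reversal the informed partner instantly re-targets;
    #: by default its box values are reflected (v <- 1 - v) because the
    #: box-to-token mapping is unchanged while the goal flips.  Setting
    #: relearn_at_reversal resets the values to 0.5 instead.
    relearn_at_reversal: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.learning_rate <= 1.0:
            raise ValueError("learning_rate must lie in [0, 1]")
        if self.inverse_temperature < 0:
            raise ValueError("inverse_temperature must be >= 0")


@dataclass
class Schedule:
    """Per-trial probability schedule for one trial list."""

    table: pd.DataFrame  # block, trial_in_block, p_a_orange, rew_prob_orange,
    #                      reversal, mag_regime
    config: TaskConfig
    list_index: int

    @property
    def n_trials(self) -> int:
        return len(self.table)

    @property
    def valuable_orange(self) -> np.ndarray:
        return (self.table["rew_prob_orange"].to_numpy() > 0.5).astype(int)


def _balanced_levels(levels: Sequence, n: int, rng: np.random.Generator) -> np.ndarray:
    """Near-balanced random assignment of condition levels to blocks."""
    reps = -(-n // len(levels))
    arr = np.array((list(levels) * reps)[:n], dtype=object)
    rng.shuffle(arr)
    return arr


def build_schedule(config: TaskConfig, list_index: int) -> Schedule:
    """Deterministically build trial list ``list_index`` under ``config``."""
    if not 0 <= list_index < config.n_trial_lists:
        raise ValueError(
            f"list_index {list_index} outside [0, {config.n_trial_lists})")
    rng = np.random.default_rng([config.rng_seed, 7919, list_index])
    tpb = config.trials_per_block

    trans_level = _balanced_levels(config.transition_levels, config.n_blocks, rng)
    mag_regime = _balanced_levels(["narrow", "wide"], config.n_blocks, rng)

    rows = []
    valuable_orange = bool(rng.integers(2))
    lo, hi = config.reversal_window
    seg_edges = np.linspace(0, tpb, config.segments_per_block + 1).astype(int)
    for b in range(config.n_blocks):
        if b > 0 and config.flip_between_blocks:
            valuable_orange = not valuable_orange
        # orange-box assignment: which box majority-delivers orange
        p = float(trans_level[b])
        p_a_orange = p if rng.integers(2) else 1.0 - p
        # one within-block reversal, uniform in the window, clipped to block
        r_pos = int(rng.integers(lo, hi + 1))
        r_pos = min(r_pos, tpb - 1)
        seg_level = [float(rng.choice(config.reward_levels))
                     for _ in range(config.segments_per_block)]
        seg_of = np.searchsorted(seg_edges[1:], np.arange(tpb), side="right")
        for t in range(tpb):
            if t == r_pos:
                valuable_orange = not valuable_orange
            level = seg_level[seg_of[t]]
            rows.append({
                "block": b,
                "trial_in_block": t,
                "p_a_orange": round(p_a_orange, 10),
                "rew_prob_orange": round(level if valuable_orange
                                         else 1.0 - level, 10),
                "reversal": int(t == r_pos),
                "mag_regime": mag_regime[b],
            })
    return Schedule(pd.DataFrame(rows), config, list_index)


def simulate_partner(schedule: Schedule, params: PartnerParams,
                     rng: np.random.Generator):
    """Simulate the informed partner over a schedule.

    Returns ``(partner_box, observed_token)`` integer arrays (box A = 0,
    orange = 1).  The partner tracks ``v`` = P(box A yields the currently
    valuable token) with a delta rule, chooses by softmax, and is told the
    valuable token, so at each reversal its box values are reflected
    (``v <- 1 - v``) or reset, per ``params.relearn_at_reversal``.
    """
    tab = schedule.table
    beta = params.inverse_temperature
    alpha = params.learning_rate
    boxes = np.empty(len(tab), dtype=np.int64)
    tokens = np.empty(len(tab), dtype=np.int64)
    v = 0.5
    for i, row in enumerate(tab.itertuples(index=False)):
        if row.trial_in_block == 0:
            v = 0.5  # new fractal pair
        elif row.reversal:
            v = 0.5 if params.relearn_at_reversal else 1.0 - v
        p_a = 1.0 / (1.0 + np.exp(-beta * (2.0 * v - 1.0)))
        box = 0 if rng.random() < p_a else 1
        p_orange = row.p_a_orange if box == 0 else 1.0 - row.p_a_orange
        token = int(rng.random() < p_orange)
        valuable_orange = row.rew_prob_orange > 0.5
        got_valuable = token == int(valuable_orange)
        if box == 0:
            v += alpha * (got_valuable - v)
        else:
            v += alpha * ((1 - got_valuable) - v)
        boxes[i] = box
        tokens[i] = token
    return boxes, tokens


def _draw_outcome(rewarded: bool, regime: str, config: TaskConfig,
                  rng: np.random.Generator) -> int:
    if not rewarded:
        return 0
    lo, hi = config.narrow_range if regime == "narrow" else config.wide_range
    return int(rng.integers(lo, hi + 1))


def generate_session(config: TaskConfig,
                     agent: Union[str, tuple] = "random",
                     rng: Optional[np.random.Generator] = None,
                     list_index: Optional[int] = None,
                     schedule: Optional[Schedule] = None,
                     partner: PartnerParams = PartnerParams(),
                     subject_id: str = "sub00") -> Session:
    """Compose schedule, partner, agent choices and outcomes into a Session.

    ``agent`` is either the string ``"random"`` (uniform chooser) or a
    ``(model_name, params_dict)`` pair naming one of the five strategy
    models.  Token screen sides are randomized per trial; the partner's box
    side is randomized too.  Unrewarded outcomes are 0 points; rewarded
    outcomes are uniform integers over the block's magnitude range.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    if schedule is None:
        if list_index is None:
            list_index = int(rng.integers(config.n_trial_lists))
        schedule = build_schedule(config, list_index)
    boxes, tokens = simulate_partner(schedule, partner, rng)
    tab = schedule.table

    n = len(tab)
    orange_left = rng.integers(2, size=n)
    box_a_left = rng.integers(2, size=n)
    partner_left = np.where(boxes == 0, box_a_left, 1 - box_a_left)

    if agent == "random":
        policy = None
    else:
        from .models import get_model
        name, pars = agent
        policy = (get_model(name), dict(pars))

    choices = np.empty(n, dtype=np.int64)
    rewarded = np.empty(n, dtype=np.int64)
    outcomes = np.empty(n, dtype=np.int64)
    state = policy[0].initial_state() if policy else None
    for i, row in enumerate(tab.itertuples(index=False)):
        ctx = {
            "block_start": row.trial_in_block == 0,
            "partner_box": int(boxes[i]),
            "observed_token": int(tokens[i]),
            "orange_left": int(orange_left[i]),
            "partner_left": int(partner_left[i]),
        }
        if policy is None:
            p_or = 0.5
        else:
            model, pars = policy
            model.observe(state, ctx, pars)
            p_or = model.prob_orange(state, ctx, pars)
        try:
            c = int(rng.random() < p_or)
        except (TypeError, ValueError) as err:  # pragma: no cover
            raise RuntimeError(f"agent simulation failed at trial {i}") from err
        p_rew = row.rew_prob_orange if c == 1 else 1.0 - row.rew_prob_orange
        r = int(rng.random() < p_rew)
        pts = _draw_outcome(bool(r), row.mag_regime, config, rng)
        if policy is not None:
            policy[0].learn(state, ctx, c, r, pts, policy[1])
        choices[i], rewarded[i], outcomes[i] = c, r, pts

    df = pd.DataFrame({
        "block": tab["block"].to_numpy(),
        "trial": np.arange(n),
        "partner_box": [BOXES[b] for b in boxes],
        "partner_side": ["left" if s else "right" for s in partner_left],
        "observed_token": [TOKENS[t] for t in tokens],
        "choice": [TOKENS[c] for c in choices],
        "outcome": outcomes,
        "orange_side": ["left" if s else "right" for s in orange_left],
        "trans_prob": tab["p_a_orange"].to_numpy(),
        "rew_prob_orange": tab["rew_prob_orange"].to_numpy(),
        "mag_regime": tab["mag_regime"].to_numpy(),
        "reversal": tab["reversal"].to_numpy(),
    })
    return Session(df, subject_id=subject_id,
                   true_model=None if agent == "random" else agent[0],
                   true_params=None if agent == "random" else dict(agent[1]))


def generate_cohort(config: TaskConfig,
                    model_mix: dict,
                    param_sampler: Callable[[str, np.random.Generator], dict],
                    rng: np.random.Generator,
                    partner: PartnerParams = PartnerParams()) -> list:
    """Generate labelled sessions: ``model_mix`` maps model name -> count.

    ``param_sampler(model_name, rng)`` draws constrained parameters.  The
    special name ``"random"`` yields uniform choosers.  Sessions carry their
    true generating model and parameters for recovery analyses.
    """
    if not model_mix or sum(model_mix.values()) == 0:
        raise ValueError("empty cohort requested")
    sessions = []
    i = 0
    for name, count in model_mix.items():
        if count < 0:
            raise ValueError(f"negative count for model {name}")
        for _ in range(count):
            if name == "random":
                agent = "random"
            else:
                agent = (name, param_sampler(name, rng))
            s = generate_session(config, agent=agent, rng=rng,
                                 partner=partner, subject_id=f"sub{i:03d}")
            sessions.append(s)
            i += 1
    return sessions
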