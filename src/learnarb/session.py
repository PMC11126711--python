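"""Trial-level container for one participant's (real or simulated) session.

Tokens are "orange"/"blue", the partner's boxes "A"/"B", screen sides
"left"/"right".  Internally orange and box A are coded 1 and 0 respectively;
a missing participant choice is coded -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

#: canonical column order of the session CSV dialect
SESSION_COLUMNS = [
    "block", "trial", "partner_box", "partner_side", "observed_token",
    "choice", "outcome", "orange_side", "trans_prob", "rew_prob_orange",
    "mag_regime", "reversal",
]

TOKENS = ("blue", "orange")   # code 0, 1
BOXES = ("A", "B")            # code 0, 1
SIDES = ("right", "left")     # code 0, 1


class SessionArrays(NamedTuple):
    """Numeric views of a session used by likelihood and signature code."""

    block: np.ndarray           # int, block id per trial
    block_start: np.ndarray     # bool, first trial of a block
    partner_box: np.ndarray     # 0 = A, 1 = B
    observed_token: np.ndarray  # 1 = orange, 0 = blue
    choice: np.ndarray          # 1 = orange, 0 = blue, -1 = missing
    rewarded: np.ndarray        # 0/1 (0 on missing-choice trials)
    outcome: np.ndarray         # points, 0-99
    orange_left: np.ndarray     # 1 if orange token displayed on the left
    partner_left: np.ndarray    # 1 if the partner's chosen box was on the left
    p_a_orange: np.ndarray      # scheduled P(box A -> orange token)
    rew_prob_orange: np.ndarray  # scheduled P(reward | orange token)
    valuable_orange: np.ndarray  # 1 if orange is the currently valuable token
    reversal: np.ndarray        # 1 on the trial where the within-block flip lands

    @property
    def n_trials(self) -> int:
        return len(self.block)


@dataclass
class Session:
    """Ordered trial records for one participant plus generating metadata."""

    trials: pd.DataFrame
    subject_id: str = "sub00"
    true_model: Optional[str] = None
    true_params: Optional[dict] = None
    flags: list = field(default_factory=list)
    _arrays: Optional[SessionArrays] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        missing = [c for c in SESSION_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"session table lacks columns: {missing}")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_blocks(self) -> int:
        return int(self.trials["block"].nunique())

    @property
    def missing_fraction(self) -> float:
        return float((self.trials["choice"] == "").mean())

    def arrays(self) -> SessionArrays:
        """Numeric encoding, cached after the first call."""
        if self._arrays is None:
            self._arrays = _encode(self.trials)
        return self._arrays

    def copy_with_choices(self, choice_code: np.ndarray,
                          rewarded: np.ndarray,
                          outcome: np.ndarray) -> "Session":
        """Return a new session with replaced choices/outcomes (for PPC)."""
        df = self.trials.copy()
        df["choice"] = [TOKENS[c] if c >= 0 else "" for c in choice_code]
        df["outcome"] = np.asarray(outcome, dtype=int)
        out = Session(df, subject_id=self.subject_id,
                      true_model=self.true_model, true_params=self.true_params)
        return out


def _encode(df: pd.DataFrame) -> SessionArrays:
    block = df["block"].to_numpy(dtype=np.int64)
    block_start = np.r_[True, block[1:] != block[:-1]]
    tok = {"orange": 1, "blue": 0}
    box = {"A": 0, "B": 1}
    side = {"left": 1, "right": 0}
    choice = np.array([tok.get(c, -1) for c in df["choice"]], dtype=np.int64)
    outcome = df["outcome"].to_numpy(dtype=np.int64)
    rewarded = ((outcome > 0) & (choice >= 0)).astype(np.int64)
    rew_p_or = df["rew_prob_orange"].to_numpy(dtype=float)
    return SessionArrays(
        block=block,
        block_start=block_start,
        partner_box=np.array([box[b] for b in df["partner_box"]], dtype=np.int64),
        observed_token=np.array([tok[t] for t in df["observed_token"]], dtype=np.int64),
        choice=choice,
        rewarded=rewarded,
        outcome=outcome,
        orange_left=np.array([side[s] for s in df["orange_side"]], dtype=np.int64),
        partner_left=np.array([side[s] for s in df["partner_side"]], dtype=np.int64),
        p_a_orange=df["trans_prob"].to_numpy(dtype=float),
        rew_prob_orange=rew_p_or,
        valuable_orange=(rew_p_or > 0.5).astype(np.int64),
        reversal=df["reversal"].to_numpy(dtype=np.int64),
    )
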