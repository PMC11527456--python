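"""Weighted up-down staircases along the evidence diagonal.

One staircase per condition (self / other) controls trial difficulty by
moving a target evidence value along the major diagonal of the rating
space.  After a correct response the staircase retreats one step toward
the incorrect-favouring side; after an error it advances 2, 2 or 3 steps
(cycling in that order) toward the correct-favouring side.  The rule
equilibrates where expected movement is zero, i.e. at accuracy

    p* = mean(up) / (mean(up) + down) = (7/3) / (7/3 + 1) = 0.7

for the 1-down / 2-2-3-up weighting.  Positions are capped at the ends of
the evidence scale, -100 and 100.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .ratings import StandardRatings

EVIDENCE_RANGE = 200.0  # full span of e = self - other on a 0-100 scale
ERROR_STEP_CYCLE = (2, 2, 3)


@dataclass(frozen=True)
class StaircaseState:
    """Immutable staircase state; :func:`update` returns a new state.

    ``sign`` is +1 for the self condition and -1 for the other condition:
    the direction along e that favours the condition's correct response.
    ``cycle_cursor`` indexes the 2-2-3 error-step cycle and only advances
    on errors.
    """

    condition: str
    position: float
    step_size: float
    sign: int
    cycle_cursor: int = 0
    error_steps: tuple[int, ...] = ERROR_STEP_CYCLE

    def __post_init__(self) -> None:
        if self.condition not in ("self", "other"):
            raise ValidationError(f"unknown condition {self.condition!r}")
        if not -100.0 <= self.position <= 100.0:
            raise ValidationError("staircase position outside [-100, 100]")
        if self.step_size <= 0:
            raise ValidationError("step size must be positive")
        if not 0 <= self.cycle_cursor < len(self.error_steps):
            raise ValidationError("cycle cursor out of range")


def init_staircase(
    condition: str,
    ratings: StandardRatings,
    step_divisor: int = 20,
    use_empirical_range: bool = False,
) -> StaircaseState:
    """Start a condition's staircase at the median evidence of the words
    favouring that condition's correct response.

    The step size is the range of e divided by ``step_divisor``; by default
    the theoretical range 200 (so step 10), optionally the empirical range
    of the participant's words.
    """
    sign = +1 if condition == "self" else -1
    e = ratings.e
    favoring = e[sign * e > 0]
    if favoring.size == 0:
        raise ValidationError(f"no words favour the {condition!r} response")
    e_range = (e.max() - e.min()) if use_empirical_range else EVIDENCE_RANGE
    return StaircaseState(
        condition=condition,
        position=float(np.median(favoring)),
        step_size=e_range / step_divisor,
        sign=sign,
    )


def update(state: StaircaseState, correct: bool) -> StaircaseState:
    """One staircase transition.

    Correct: one step toward the incorrect-favouring side, error cycle
    untouched.  Error: the current cycle value (2, 2 or 3) of steps toward
    the correct-favouring side, then the cycle advances.  The new position
    is clamped to [-100, 100].
    """
    if correct:
        pos = state.position - state.sign * state.step_size
        cursor = state.cycle_cursor
    else:
        k = state.error_steps[state.cycle_cursor]
        pos = state.position + state.sign * k * state.step_size
        cursor = (state.cycle_cursor + 1) % len(state.error_steps)
    pos = float(np.clip(pos, -100.0, 100.0))
    return replace(state, position=pos, cycle_cursor=cursor)


def equilibrium_accuracy(
    down_steps: float = 1.0, up_steps: Sequence[float] = ERROR_STEP_CYCLE
) -> float:
    """Accuracy at which the staircase's expected movement is zero.

    Balance p * down = (1 - p) * mean(up) gives
    p = mean(up) / (mean(up) + down).
    """
    up = np.asarray(up_steps, dtype=float)
    if down_steps <= 0 or up.size == 0 or np.any(up <= 0):
        raise ValidationError("staircase steps must be positive")
    u = up.mean()
    return float(u / (u + down_steps))
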