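"""Bisection threshold staircase.

Each test location keeps an interval ``[lower, upper]`` of candidate
sensitivities, initially the nominal test range [14, 40] dB.  Every
presentation shows the interval midpoint (or, on the very first
presentation, an optional seed inherited from the central threshold).  A
*seen* response means the patient's sensitivity is at least the presented
attenuation, so the lower bound rises to it; *not seen* lowers the upper
bound.  Testing stops once the interval is narrower than 1 dB and the final
threshold is the midpoint of the terminal interval.

From the full 26-dB range with no seed the interval width halves each
presentation (26 → 13 → 6.5 → 3.25 → 1.625 → 0.8125), so an unseeded
staircase always terminates after exactly five presentations, and the
estimate of a deterministic observer is within 0.40625 dB (half the terminal
width) of the true threshold.

The state machine is pure: :func:`update` returns a new state, and the
presented sequence depends only on the response sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

__all__ = [
    "ThresholdState",
    "StaircaseError",
    "init_state",
    "next_intensity",
    "update",
    "final_threshold",
    "TERMINATION_WIDTH_DB",
]

#: Terminate when upper - lower drops below this (dB).
TERMINATION_WIDTH_DB = 1.0


class StaircaseError(RuntimeError):
    """Raised when an operation is invalid for the current staircase state."""


@dataclass(frozen=True)
class ThresholdState:
    """Immutable per-location staircase state.

    ``presentations`` is the ordered history of (intensity dB, seen) pairs.
    ``floored`` / ``ceilinged`` indicate that a bound never moved off its
    initial value, i.e. the true threshold may lie outside the test range.
    """

    lower: float
    upper: float
    seed: Optional[float] = None
    presentations: tuple[tuple[float, bool], ...] = ()
    initial_lower: float = 14.0
    initial_upper: float = 40.0

    @property
    def width(self) -> float:
        return self.upper - self.lower

    @property
    def terminated(self) -> bool:
        return self.width < TERMINATION_WIDTH_DB

    @property
    def floored(self) -> bool:
        """True if the lower bound never moved (threshold may be below range)."""
        return self.lower == self.initial_lower

    @property
    def ceilinged(self) -> bool:
        """True if the upper bound never moved (threshold may be above range)."""
        return self.upper == self.initial_upper


def init_state(
    lower: float = 14.0, upper: float = 40.0, seed: Optional[float] = None
) -> ThresholdState:
    """Create a fresh staircase on ``[lower, upper]`` with an optional seed.

    The seed sets only the *first presented intensity*; the search interval
    remains the full range.  A seed outside the interval is rejected with
    ``ValueError`` — callers should fall back to an unseeded staircase.
    """
    if not lower < upper:
        raise ValueError(f"need lower < upper, got [{lower}, {upper}]")
    if seed is not None and not (lower <= seed <= upper):
        raise ValueError(f"seed {seed} outside [{lower}, {upper}]")
    return ThresholdState(
        lower=lower, upper=upper, seed=seed, initial_lower=lower, initial_upper=upper
    )


def next_intensity(state: ThresholdState) -> float:
    """Intensity (dB) to present next: the seed on the first trial, else the midpoint."""
    if state.terminated:
        raise StaircaseError("staircase already terminated")
    if not state.presentations and state.seed is not None:
        return state.seed
    return (state.lower + state.upper) / 2.0


def update(state: ThresholdState, presented: float, seen: bool) -> ThresholdState:
    """Fold one response into the staircase; returns the new state.

    Seen raises the lower bound to the presented attenuation (sensitivity is
    at least that good); not seen lowers the upper bound.
    """
    if state.terminated:
        raise StaircaseError("cannot update a terminated staircase")
    if not (state.lower - 1e-9 <= presented <= state.upper + 1e-9):
        raise ValueError(
            f"presented intensity {presented} outside current interval "
            f"[{state.lower}, {state.upper}]"
        )
    if seen:
        new_lower, new_upper = presented, state.upper
    else:
        new_lower, new_upper = state.lower, presented
    return replace(
        state,
        lower=new_lower,
        upper=new_upper,
        presentations=state.presentations + ((presented, seen),),
    )


def final_threshold(state: ThresholdState) -> float:
    """Final threshold sensitivity: midpoint of the terminal interval.

    Only valid once the staircase has terminated; check ``state.floored`` /
    ``state.ceilinged`` to see whether the estimate hit a range limit.
    """
    if not state.terminated:
        raise StaircaseError("staircase has not terminated")
    return (state.lower + state.upper) / 2.0
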