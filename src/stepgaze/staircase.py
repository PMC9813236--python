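"""Interleaved 3-down/1-up staircase for orientation-discrimination thresholds.

The transformed up-down rule decreases the Gabor tilt by one step after three
consecutive correct responses and increases it after any error, which makes
the procedure converge on the stimulus level where p(correct)^3 = 0.5, i.e.
p ~ 0.794 ("79%").  Each of the four walkway locations runs its own track;
trials are drawn uniformly among unterminated tracks.  A track terminates at
its sixth reversal and its threshold is the mean of the last four reversal
levels (Levitt-style estimator).

Conventions (the source protocol leaves these open, so they are fixed here):

* The three-correct counter resets after *every* adjustment, up or down.
* A "reversal level" is the level being adjusted away from, i.e. the level at
  which the direction change occurs.
* Levels are floored at one step size (0.3 deg).  A down-move at the floor
  holds the level but logs a "bounce" reversal at the floor, so even an
  error-free responder terminates (at a threshold equal to the floor) instead
  of descending forever.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .trial_design import ARROW_CUES, LOCATIONS, SIDES

#: Percent-correct fixed point of the 3-down/1-up rule: 0.5 ** (1/3).
TARGET_P = 0.5 ** (1.0 / 3.0)

DOWN = "down"
UP = "up"
NONE = "none"


class StaircaseUsageError(RuntimeError):
    """Update on a terminated track, or threshold before termination."""


@dataclass
class StaircaseState:
    """Mutable state of one staircase track."""

    level: float = 6.0
    step_size: float = 0.3
    floor: float = 0.3
    n_reversals_to_stop: int = 6
    consecutive_correct: int = 0
    reversal_levels: list[float] = field(default_factory=list)
    last_direction: str = NONE
    terminated: bool = False
    n_trials: int = 0


@dataclass(frozen=True)
class StaircaseResult:
    location: str
    threshold: float
    n_trials: int
    reversal_levels: tuple[float, ...]
    terminated: bool = True


def staircase_update(state: StaircaseState, response_correct: bool) -> StaircaseState:
    """Apply one trial's response to a track (mutates and returns ``state``).

    Three consecutive correct responses move the level down one step; any
    error moves it up one step.  A reversal is logged whenever the adjustment
    direction flips, and the track terminates once the configured reversal
    count is reached.
    """
    if state.terminated:
        raise StaircaseUsageError("staircase_update called on a terminated track")
    state.n_trials += 1
    if response_correct:
        state.consecutive_correct += 1
        direction = DOWN if state.consecutive_correct >= 3 else None
    else:
        direction = UP
    if direction is None:
        return state
    logged = False
    if state.last_direction != NONE and direction != state.last_direction:
        state.reversal_levels.append(state.level)
        logged = True
    if direction == DOWN:
        new_level = round(state.level - state.step_size, 10)
        if new_level < state.floor - 1e-9:
            # Floor bounce: the down-move is held at the floor but still logs
            # a reversal, so even an error-free responder terminates.
            if not logged:
                state.reversal_levels.append(state.level)
        else:
            state.level = new_level
    else:
        state.level = round(state.level + state.step_size, 10)
    state.last_direction = direction
    state.consecutive_correct = 0
    if len(state.reversal_levels) >= state.n_reversals_to_stop:
        state.terminated = True
    return state


def staircase_threshold(state: StaircaseState) -> float:
    """Mean of the last four reversal levels of a terminated track."""
    if not state.terminated:
        raise StaircaseUsageError(
            f"threshold requested with only {len(state.reversal_levels)} reversals")
    return float(np.mean(state.reversal_levels[-4:]))


def run_staircase(p_correct, seed: int | np.random.Generator = 0,
                  start: float = 6.0, step_size: float = 0.3,
                  floor: float = 0.3, n_reversals: int = 6,
                  max_trials: int = 1000) -> StaircaseState:
    """Run a single track against a response model.

    ``p_correct`` maps an orientation magnitude (deg) to the probability of a
    correct discrimination.  Returns the final state (terminated unless the
    trial cap was hit).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = StaircaseState(level=start, step_size=step_size, floor=floor,
                           n_reversals_to_stop=n_reversals)
    while not state.terminated and state.n_trials < max_trials:
        staircase_update(state, bool(rng.random() < p_correct(state.level)))
    return state


@dataclass(frozen=True)
class InterleavedOutcome:
    results: dict[str, StaircaseResult]
    trace: pd.DataFrame
    n_trials: int
    capped: bool = False


def run_interleaved_thresholding(observer, locations=LOCATIONS, *,
                                 start: float = 6.0, step_size: float = 0.3,
                                 floor: float = 0.3, n_reversals: int = 6,
                                 seed: int | np.random.Generator = 0,
                                 max_total_trials: int = 4000) -> InterleavedOutcome:
    """Interleave one 3-down/1-up track per location until all terminate.

    ``observer`` must expose ``p_correct(orientation_deg, location)``; each
    trial draws uniformly among unterminated tracks, randomizes the cue
    direction and tilt side (recorded in the trace; they do not enter the
    response model beyond the observer's own bias), and updates that track.
    Tracks that fail to terminate within the cap are returned partial with
    ``capped=True``.
    """
    import warnings

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = {loc: StaircaseState(level=start, step_size=step_size, floor=floor,
                                  n_reversals_to_stop=n_reversals)
              for loc in locations}
    rows = []
    total = 0
    while True:
        open_tracks = [loc for loc, s in states.items() if not s.terminated]
        if not open_tracks or total >= max_total_trials:
            break
        loc = open_tracks[rng.integers(len(open_tracks))]
        state = states[loc]
        level = state.level
        cue = ARROW_CUES[rng.integers(2)]
        side = SIDES[rng.integers(2)]
        correct = bool(rng.random() < observer.p_correct(level, loc))
        n_rev_before = len(state.reversal_levels)
        staircase_update(state, correct)
        total += 1
        rows.append({"trial": total, "location": loc, "level": level, "cue": cue,
                     "gabor_side": side, "correct": correct,
                     "reversal": len(state.reversal_levels) > n_rev_before})
    capped = any(not s.terminated for s in states.values())
    if capped:
        warnings.warn("staircase trial cap reached; returning partial thresholds",
                      RuntimeWarning, stacklevel=2)
    results = {}
    for loc, s in states.items():
        thr = (staircase_threshold(s) if s.terminated
               else float(np.mean(s.reversal_levels[-4:])) if s.reversal_levels
               else s.level)
        results[loc] = StaircaseResult(location=loc, threshold=thr,
                                       n_trials=s.n_trials,
                                       reversal_levels=tuple(s.reversal_levels),
                                       terminated=s.terminated)
    return InterleavedOutcome(results=results, trace=pd.DataFrame(rows),
                              n_trials=total, capped=capped)
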