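"""Experimental schedule generation for the cued obstacle-crossing task.

A session interleaves obstacle-crossing trials (a left or right arrow cue
indicates the first stepping leg) with stationary trials (horizontal-bar cue).
A Gabor patch is flashed at one of four walkway locations (R1, L1, R2, L2),
tilted left or right of vertical by that location's 79%-discrimination
threshold.  The cue determines which locations the feet will land on and hence
whether each Gabor location is *stepping* or *non-stepping* on that trial.

Timing constants: the Gabor appears 300 ms after cue onset (cue-test
interval), lasts 77.8 ms, and the fixation cross/cue disappear 44.4 ms after
Gabor offset.  Step onset must fall between the Gabor offset (377.8 ms) and
1000 ms after cue onset for a crossing trial to count.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

LOCATIONS: tuple[str, ...] = ("R1", "L1", "R2", "L2")

CONDITION_CROSSING = "crossing"
CONDITION_STATIONARY = "stationary"

CUE_LEFT = "left_arrow"
CUE_RIGHT = "right_arrow"
CUE_BAR = "horizontal_bar"
ARROW_CUES = (CUE_LEFT, CUE_RIGHT)

RELEVANCE_STEPPING = "stepping"
RELEVANCE_NON_STEPPING = "non_stepping"
RELEVANCE_NA = "not_applicable"

SIDES = ("left", "right")

#: Stepping locations implied by each arrow cue.  A rightward arrow means the
#: right leg steps first (into R1) and the left leg second (into L2); the
#: leftward arrow mirrors this.
STEPPING_SETS: dict[str, frozenset[str]] = {
    CUE_RIGHT: frozenset({"R1", "L2"}),
    CUE_LEFT: frozenset({"L1", "R2"}),
}

#: Step index of each walkway location (first or second step of the approach).
STEP_OF_LOCATION: dict[str, str] = {"R1": "step1", "L1": "step1", "R2": "step2", "L2": "step2"}


class ScheduleConfigError(ValueError):
    """Raised when session counts cannot satisfy the balance constraints."""


@dataclass(frozen=True)
class SessionConfig:
    """Counts and timing constants of one experimental session.

    Durations are milliseconds.  ``step_onset_min`` is not free: it equals
    ``cue_test_interval + gabor_duration`` (the Gabor offset time).
    """

    n_blocks: int = 4
    walking_trials_per_block: int = 48
    stationary_trials_per_block: int = 24
    cue_test_interval: float = 300.0
    gabor_duration: float = 77.8
    cross_cue_offset_delay: float = 44.4
    step_onset_max: float = 1000.0
    fixation_duration: float = 500.0
    seed: int = 0
    balance_tilt: bool = True  # balance Gabor tilt side within each cell

    @property
    def step_onset_min(self) -> float:
        """Earliest admissible step onset: the Gabor offset time."""
        return self.cue_test_interval + self.gabor_duration

    @property
    def cross_offset(self) -> float:
        """Fixation-cross/cue offset time relative to cue onset."""
        return self.step_onset_min + self.cross_cue_offset_delay

    @property
    def locations(self) -> tuple[str, ...]:
        return LOCATIONS

    def validate(self) -> None:
        for name in ("cue_test_interval", "gabor_duration", "cross_cue_offset_delay",
                     "step_onset_max", "fixation_duration"):
            if getattr(self, name) <= 0:
                raise ScheduleConfigError(f"{name} must be positive")
        if self.n_blocks < 1:
            raise ScheduleConfigError("n_blocks must be >= 1")
        n_cells = len(LOCATIONS) * len(ARROW_CUES)
        if self.walking_trials_per_block % n_cells:
            raise ScheduleConfigError(
                f"walking_trials_per_block={self.walking_trials_per_block} is not "
                f"divisible by {n_cells} (4 locations x 2 arrow cues)")
        if self.stationary_trials_per_block % len(LOCATIONS):
            raise ScheduleConfigError(
                f"stationary_trials_per_block={self.stationary_trials_per_block} is "
                f"not divisible by {len(LOCATIONS)} locations")


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial."""

    trial_id: int
    block: int
    condition: str
    cue: str
    gabor_location: str
    gabor_side: str
    gabor_orientation: float

    def __post_init__(self) -> None:
        if (self.condition == CONDITION_STATIONARY) != (self.cue == CUE_BAR):
            raise ValueError("stationary condition iff horizontal_bar cue")
        if self.gabor_orientation <= 0:
            raise ValueError("gabor_orientation must be positive")


@dataclass(frozen=True)
class RelevanceAssignment:
    relevance: str
    step: str


def assign_relevance(cue: str, gabor_location: str) -> RelevanceAssignment:
    """Map (cue, Gabor location) to task relevance and step index.

    Right-arrow trials step on R1 and L2 (so those are the stepping
    locations); left-arrow trials mirror this.  Stationary (horizontal-bar)
    trials have no stepping locations, so relevance is not applicable.
    """
    if gabor_location not in LOCATIONS:
        raise ValueError(f"unknown location {gabor_location!r}")
    step = STEP_OF_LOCATION[gabor_location]
    if cue == CUE_BAR:
        return RelevanceAssignment(RELEVANCE_NA, step)
    if cue not in STEPPING_SETS:
        raise ValueError(f"unknown cue {cue!r}")
    relevance = (RELEVANCE_STEPPING if gabor_location in STEPPING_SETS[cue]
                 else RELEVANCE_NON_STEPPING)
    return RelevanceAssignment(relevance, step)


def _balanced_sides(n: int, rng: np.random.Generator, balance: bool) -> list[str]:
    if not balance:
        return [SIDES[i] for i in rng.integers(0, 2, size=n)]
    sides = ["left"] * (n // 2) + ["right"] * (n // 2)
    if n % 2:  # parity leftover assigned at random
        sides.append(SIDES[rng.integers(0, 2)])
    rng.shuffle(sides)
    return sides


def generate_session(config: SessionConfig,
                     thresholds: Mapping[str, float]) -> list[TrialSpec]:
    """Enumerate and shuffle the balanced trial list for a whole session.

    Per block each location receives ``walking/8`` crossing trials with each
    arrow cue and ``stationary/4`` horizontal-bar trials; tilt side is
    balanced within every (location, cue, condition) cell up to parity.  The
    within-block order is a seeded uniform shuffle, so the schedule is a pure
    function of (config, thresholds, seed).
    """
    config.validate()
    missing = [loc for loc in LOCATIONS if loc not in thresholds]
    if missing:
        raise ScheduleConfigError(f"thresholds missing for locations {missing}")
    for loc in LOCATIONS:
        if thresholds[loc] <= 0:
            raise ScheduleConfigError(f"threshold for {loc} must be positive")

    per_cell_walk = config.walking_trials_per_block // (len(LOCATIONS) * len(ARROW_CUES))
    per_loc_stat = config.stationary_trials_per_block // len(LOCATIONS)

    trials: list[TrialSpec] = []
    trial_id = 0
    for block in range(config.n_blocks):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, block]))
        rows: list[tuple[str, str, str, str]] = []  # condition, cue, location, side
        for loc in LOCATIONS:
            for cue in ARROW_CUES:
                for side in _balanced_sides(per_cell_walk, rng, config.balance_tilt):
                    rows.append((CONDITION_CROSSING, cue, loc, side))
            for side in _balanced_sides(per_loc_stat, rng, config.balance_tilt):
                rows.append((CONDITION_STATIONARY, CUE_BAR, loc, side))
        order = rng.permutation(len(rows))
        for idx in order:
            condition, cue, loc, side = rows[idx]
            trials.append(TrialSpec(
                trial_id=trial_id, block=block, condition=condition, cue=cue,
                gabor_location=loc, gabor_side=side,
                gabor_orientation=float(thresholds[loc])))
            trial_id += 1
    return trials


def schedule_frame(trials: Sequence[TrialSpec]) -> pd.DataFrame:
    """Tabulate a schedule, adding derived relevance/step columns."""
    records = []
    for t in trials:
        ra = assign_relevance(t.cue, t.gabor_location)
        rec = dataclasses.asdict(t)
        rec["relevance"] = ra.relevance
        rec["step"] = ra.step
        records.append(rec)
    return pd.DataFrame.from_records(records)


def schedule_from_frame(df: pd.DataFrame) -> list[TrialSpec]:
    cols = [f.name for f in dataclasses.fields(TrialSpec)]
    return [TrialSpec(**{c: row[c] for c in cols}) for _, row in df.iterrows()]
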