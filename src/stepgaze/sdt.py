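"""Signal-detection scoring of orientation-discrimination responses.

Responses are classified against the (arbitrary) convention that a
right-tilted Gabor is the "signal": a correct response to a right tilt is a
hit, an incorrect one a miss; a correct response to a left tilt is a correct
rejection, an incorrect one a false alarm.  Per analysis cell,

    percent correct = 100 * (hits + CR) / N                 (raw counts)
    hit rate  = (hits + 0.5) / (hits + misses + 1)          (log-linear rule)
    FA rate   = (FA + 0.5) / (FA + CR + 1)
    d'        = Z(hit rate) - Z(FA rate)
    beta      = exp((Z(FA rate)^2 - Z(hit rate)^2) / 2)

with Z the standard-normal quantile.  The log-linear correction is applied to
every cell unconditionally, which keeps rates strictly inside (0, 1) and d'
finite.  beta = 1 is unbiased; beta < 1 a "right" bias, beta > 1 a "left"
bias.

Crossing trials are binned into the four relevance x step cells; stationary
trials only by step (relevance is undefined without a stepping cue).  Change
(Δ) scores subtract the stationary score from the crossing score matched on
step, so negative Δ means performance was better while stationary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .trial_design import (CONDITION_CROSSING, CONDITION_STATIONARY,
                           RELEVANCE_NA, RELEVANCE_NON_STEPPING,
                           RELEVANCE_STEPPING, assign_relevance)

HIT = "hit"
MISS = "miss"
CORRECT_REJECTION = "correct_rejection"
FALSE_ALARM = "false_alarm"

OUTCOMES = ("percent_correct", "d_prime", "beta")


class DegenerateCellWarning(UserWarning):
    pass


@dataclass(frozen=True)
class SDTCounts:
    hits: int = 0
    misses: int = 0
    correct_rejections: int = 0
    false_alarms: int = 0

    def __post_init__(self) -> None:
        if min(self.hits, self.misses, self.correct_rejections, self.false_alarms) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.hits + self.misses + self.correct_rejections + self.false_alarms


@dataclass(frozen=True)
class SDTScores:
    percent_correct: float
    hit_rate: float
    fa_rate: float
    d_prime: float
    beta: float


def classify_response(gabor_side: str, reported_side: str) -> str:
    """Hit/miss/CR/FA classification with right tilt as the signal."""
    for name, value in (("gabor_side", gabor_side), ("reported_side", reported_side)):
        if value not in ("left", "right"):
            raise ValueError(f"{name} must be 'left' or 'right', got {value!r}")
    if gabor_side == "right":
        return HIT if reported_side == "right" else MISS
    return CORRECT_REJECTION if reported_side == "left" else FALSE_ALARM


def compute_rates(counts: SDTCounts) -> tuple[float, float]:
    """Log-linear corrected hit and false-alarm rates (always in (0,1))."""
    if counts.hits + counts.misses == 0 or counts.false_alarms + counts.correct_rejections == 0:
        warnings.warn("degenerate SDT cell: no signal or no noise trials",
                      DegenerateCellWarning, stacklevel=2)
    hit_rate = (counts.hits + 0.5) / (counts.hits + counts.misses + 1.0)
    fa_rate = (counts.false_alarms + 0.5) / (counts.false_alarms + counts.correct_rejections + 1.0)
    return hit_rate, fa_rate


def compute_scores(counts: SDTCounts) -> SDTScores:
    """Percent correct (raw counts), d' and beta (corrected rates)."""
    hit_rate, fa_rate = compute_rates(counts)
    z_hit = norm.ppf(hit_rate)
    z_fa = norm.ppf(fa_rate)
    if counts.total:
        pc = 100.0 * (counts.hits + counts.correct_rejections) / counts.total
    else:
        pc = float("nan")
    return SDTScores(percent_correct=pc, hit_rate=hit_rate, fa_rate=fa_rate,
                     d_prime=float(z_hit - z_fa),
                     beta=float(np.exp((z_fa ** 2 - z_hit ** 2) / 2.0)))


def counts_from_records(df: pd.DataFrame) -> SDTCounts:
    cls = [classify_response(g, r)
           for g, r in zip(df["gabor_side"], df["reported_side"])]
    cls = pd.Series(cls)
    return SDTCounts(hits=int((cls == HIT).sum()),
                     misses=int((cls == MISS).sum()),
                     correct_rejections=int((cls == CORRECT_REJECTION).sum()),
                     false_alarms=int((cls == FALSE_ALARM).sum()))


def _ensure_cell_columns(records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    if "relevance" not in df.columns or "step" not in df.columns:
        ra = [assign_relevance(c, g) for c, g in zip(df["cue"], df["gabor_location"])]
        df["relevance"] = [a.relevance for a in ra]
        df["step"] = [a.step for a in ra]
    return df


def bin_and_score(records: pd.DataFrame,
                  qc: pd.DataFrame | None = None,
                  timing: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-participant SDT scores for every analysis cell.

    ``records`` needs columns participant, trial_id, condition, cue,
    gabor_location, gabor_side, reported_side (relevance/step are derived if
    absent).  ``qc`` (trial_id, passed) and ``timing`` (trial_id, timing)
    restrict the tally to trials that passed gaze QC and — for crossing
    trials — have a valid step-onset time.  Crossing trials fill the four
    relevance x step cells; stationary trials the two step cells.
    """
    df = _ensure_cell_columns(records)

    def keys(frame: pd.DataFrame, rows: pd.DataFrame) -> pd.Series | set:
        if "participant" in frame.columns:
            return set(zip(rows["participant"], rows["trial_id"]))
        return set(rows["trial_id"])

    def df_keys(frame: pd.DataFrame):
        if "participant" in frame.columns:
            return pd.Series(list(zip(df["participant"], df["trial_id"])), index=df.index)
        return df["trial_id"]

    if qc is not None:
        ok = keys(qc, qc.loc[qc["passed"].astype(bool)])
        df = df[df_keys(qc).isin(ok)]
    if timing is not None:
        valid = keys(timing, timing.loc[timing["timing"] == "valid"])
        crossing = df["condition"] == CONDITION_CROSSING
        df = df[~crossing | df_keys(timing).isin(valid)]

    rows = []
    for participant, pdf in df.groupby("participant"):
        cells: list[tuple[str, str, str, pd.DataFrame]] = []
        cross = pdf[pdf["condition"] == CONDITION_CROSSING]
        for rel in (RELEVANCE_STEPPING, RELEVANCE_NON_STEPPING):
            for step in ("step1", "step2"):
                cells.append((CONDITION_CROSSING, rel, step,
                              cross[(cross["relevance"] == rel) & (cross["step"] == step)]))
        stat = pdf[pdf["condition"] == CONDITION_STATIONARY]
        for step in ("step1", "step2"):
            cells.append((CONDITION_STATIONARY, RELEVANCE_NA, step,
                          stat[stat["step"] == step]))
        for condition, rel, step, cell_df in cells:
            counts = counts_from_records(cell_df)
            scores = compute_scores(counts)
            rows.append({"participant": participant, "condition": condition,
                         "relevance": rel, "step": step, "n_trials": counts.total,
                         "hits": counts.hits, "misses": counts.misses,
                         "correct_rejections": counts.correct_rejections,
                         "false_alarms": counts.false_alarms,
                         "hit_rate": scores.hit_rate, "fa_rate": scores.fa_rate,
                         "percent_correct": scores.percent_correct,
                         "d_prime": scores.d_prime, "beta": scores.beta})
    return pd.DataFrame(rows)


def compute_change_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Crossing-minus-stationary Δ scores per participant and crossing cell.

    The stationary reference is matched on step only.  Raises ``KeyError``
    naming the missing (participant, step) stationary cell if absent.
    """
    stat = scores[scores["condition"] == CONDITION_STATIONARY]
    ref = {(p, s): row for (p, s), row in
           stat.set_index(["participant", "step"]).iterrows()}
    rows = []
    cross = scores[scores["condition"] == CONDITION_CROSSING]
    for _, row in cross.iterrows():
        key = (row["participant"], row["step"])
        if key not in ref:
            raise KeyError(f"missing stationary reference cell {key}")
        base = ref[key]
        rows.append({"participant": row["participant"],
                     "relevance": row["relevance"], "step": row["step"],
                     "delta_percent_correct": row["percent_correct"] - base["percent_correct"],
                     "delta_d_prime": row["d_prime"] - base["d_prime"],
                     "delta_beta": row["beta"] - base["beta"]})
    return pd.DataFrame(rows)
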