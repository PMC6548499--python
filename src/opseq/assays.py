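"""Derived per-experiment measures.

Builds the tables behind the standard analyses: CS/pre-CS period response
tables and PIT scores from transfer tests, extinction-phase devaluation
tables from two-lever tests, Pavlovian conditioning scores, and per-subject
feedback-condition summaries.

Window conventions: a CS window is the closed 120 s interval
``[onset, offset]`` (a press exactly at onset belongs to the CS period);
its pre-CS window is the open 120 s interval ``(onset - 120, onset)``.
PIT scores are totals over the four trials per cue type, not per-trial
means. Proportions over zero presses are undefined (``NaN``), never zero,
and are excluded from downstream proportion analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events_io import SessionLog, ValidationError
from .microstructure import ClassifiedPress, detect_noncontingent_approaches

__all__ = [
    "TrialWindow",
    "extract_cs_windows",
    "period_response_table",
    "pit_score",
    "cno_suppression",
    "devaluation_table",
    "pavlovian_conditioning_score",
    "feedback_summary",
    "collapse_pre_periods",
    "average_repeated_tests",
]

PRE_CS_S = 120.0
DEVAL_PHASE_END_S = 300.0


@dataclass(frozen=True)
class TrialWindow:
    """One CS presentation with its 120 s pre-CS baseline window."""

    cs_type: str
    onset_s: float
    offset_s: float

    @property
    def pre_onset_s(self) -> float:
        return self.onset_s - PRE_CS_S

    def contains(self, t: float) -> bool:
        return self.onset_s <= t <= self.offset_s

    def pre_contains(self, t: float) -> bool:
        return self.pre_onset_s < t < self.onset_s


def extract_cs_windows(log: SessionLog, expect_n: int | None = None) -> list[TrialWindow]:
    """Pair CS onsets/offsets into trial windows.

    For ``pit_test`` sessions exactly 8 presentations are required (4 CS+,
    4 CS-). Raises if any pre-CS window would overlap the preceding CS
    (cannot occur with the standard 180 s ITI) or if onsets/offsets are
    unbalanced.
    """
    onsets = [(e.time_s, e.arg) for e in log.events if e.event_type == "cs_onset"]
    offsets = [(e.time_s, e.arg) for e in log.events if e.event_type == "cs_offset"]
    if len(onsets) != len(offsets):
        raise ValidationError(
            f"{log.session_id}: {len(onsets)} cs_onset vs {len(offsets)} cs_offset events"
        )
    windows = [
        TrialWindow(cue, on, off_t)
        for (on, cue), (off_t, _) in zip(onsets, offsets)
    ]
    if expect_n is None and log.session_type == "pit_test":
        expect_n = 8
    if expect_n is not None and len(windows) != expect_n:
        raise ValidationError(
            f"{log.session_id}: expected {expect_n} CS presentations, found {len(windows)}"
        )
    for prev, w in zip(windows, windows[1:]):
        if w.pre_onset_s < prev.offset_s:
            raise ValidationError(
                f"{log.session_id}: pre-CS window of trial at {w.onset_s} overlaps "
                f"the preceding CS (offset {prev.offset_s})"
            )
    return windows


def period_response_table(
    log: SessionLog,
    windows: list[TrialWindow],
    classified: list[ClassifiedPress],
    cutoff_s: float | None = None,
) -> pd.DataFrame:
    """Per-period response counts, summed over the trials of each cue type.

    Rows are keyed by (subject, session, cs_type, period) with period "CS"
    or "preCS"; columns hold press counts split by contingent-approach
    status, noncontingent bout counts, and the proportion of presses
    followed by approach (NaN when the period has no presses). Events
    outside every window are excluded.
    """
    kwargs = {} if cutoff_s is None else {"cutoff_s": cutoff_s}
    bouts = detect_noncontingent_approaches(log, **kwargs)
    rows = []
    cs_types = sorted({w.cs_type for w in windows})
    for cs_type in cs_types:
        ws = [w for w in windows if w.cs_type == cs_type]
        for period, member in (
            ("CS", lambda t, ws=ws: any(w.contains(t) for w in ws)),
            ("preCS", lambda t, ws=ws: any(w.pre_contains(t) for w in ws)),
        ):
            sel = [c for c in classified if member(c.press_time_s)]
            n = len(sel)
            n_with = sum(c.with_approach for c in sel)
            rows.append(
                {
                    "subject_id": log.subject_id,
                    "session_id": log.session_id,
                    "cs_type": cs_type,
                    "period": period,
                    "press_count": n,
                    "presses_with_approach": n_with,
                    "presses_without_approach": n - n_with,
                    "noncontingent_bouts": sum(member(b.start_time_s) for b in bouts),
                    "proportion_with_approach": (n_with / n) if n else np.nan,
                }
            )
    return pd.DataFrame(rows)


def collapse_pre_periods(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse preCS+ and preCS- rows into a single three-level period factor.

    Returns rows with ``cs_period`` in {"CS+", "CS-", "Pre-CS"} for the
    proportion analysis; count columns are summed across the two pre-CS
    periods, and the proportion recomputed from the pooled counts.
    """
    t = table.copy()
    t["cs_period"] = np.where(t["period"] == "CS", t["cs_type"], "Pre-CS")
    agg = (
        t.groupby(["subject_id", "session_id", "cs_period"], as_index=False)[
            ["press_count", "presses_with_approach", "presses_without_approach",
             "noncontingent_bouts"]
        ].sum()
    )
    agg["proportion_with_approach"] = np.where(
        agg["press_count"] > 0,
        agg["presses_with_approach"] / agg["press_count"].replace(0, np.nan),
        np.nan,
    )
    return agg


_FILTER_COLUMNS = {
    "all": "press_count",
    "with_approach": "presses_with_approach",
    "without_approach": "presses_without_approach",
}


def pit_score(table: pd.DataFrame, press_filter: str = "all") -> int:
    """PIT score: total (filtered) presses in CS+ periods minus pre-CS+ periods."""
    col = _FILTER_COLUMNS[press_filter]
    plus = table[table["cs_type"] == "CS+"]
    cs = int(plus.loc[plus["period"] == "CS", col].sum())
    pre = int(plus.loc[plus["period"] == "preCS", col].sum())
    if plus.empty:
        raise ValueError("table has no CS+ rows")
    return cs - pre


def cno_suppression(score_cno: float, score_vehicle: float) -> float:
    """Drug-induced change in the PIT score (CNO test minus vehicle test)."""
    return score_cno - score_vehicle


def average_repeated_tests(scores: pd.DataFrame, value_col: str = "score") -> pd.DataFrame:
    """Average per-subject scores across repeated tests of the same drug.

    For designs with two tests per drug condition, reduces to one value per
    (subject, drug) before group statistics.
    """
    return scores.groupby(["subject_id", "drug"], as_index=False)[value_col].mean()


def devaluation_table(
    log: SessionLog,
    classified: list[ClassifiedPress],
    phase_end_s: float = DEVAL_PHASE_END_S,
) -> pd.DataFrame:
    """Extinction-phase counts and proportions per lever and press type.

    Rows per lever value ("valued"/"devalued") and press type
    ("with_approach", "without_approach", "all") with the press count in the
    first ``phase_end_s`` seconds and, for the "all" rows, the proportion of
    those presses followed by approach. Presses after the phase boundary are
    excluded.
    """
    if log.session_type != "devaluation_test":
        raise ValidationError(f"{log.session_id}: not a devaluation_test session")
    phase = [c for c in classified if 0 < c.press_time_s <= phase_end_s]
    levers = sorted({c.arg for c in phase} | {"valued", "devalued"})
    drug = log.condition_tags.get("drug", "")
    rows = []
    for lever in levers:
        sel = [c for c in phase if c.arg == lever]
        n = len(sel)
        n_with = sum(c.with_approach for c in sel)
        for press_type, count in (
            ("with_approach", n_with),
            ("without_approach", n - n_with),
            ("all", n),
        ):
            rows.append(
                {
                    "subject_id": log.subject_id,
                    "session_id": log.session_id,
                    "drug": drug,
                    "lever": lever,
                    "press_type": press_type,
                    "press_count": count,
                    "proportion_with_approach": (n_with / n) if n else np.nan,
                }
            )
    return pd.DataFrame(rows)


def pavlovian_conditioning_score(log: SessionLog) -> pd.DataFrame:
    """Per-trial food-cup entry rates (entries/min) for CS and pre-CS periods.

    The CS rate is computed from cue onset to the first pellet delivery of
    the trial, excluding pellet-driven (unconditioned) retrieval; trials
    with no pellet use the full CS window. The pre-CS rate covers the 120 s
    before onset.
    """
    if log.session_type != "pavlovian":
        raise ValidationError(f"{log.session_id}: not a pavlovian session")
    windows = extract_cs_windows(log)
    entries = np.asarray(log.entry_times)
    pellets = np.asarray(log.times("pellet_delivery"))
    rows = []
    for i, w in enumerate(windows):
        in_cs = pellets[(pellets > w.onset_s) & (pellets <= w.offset_s)]
        cs_end = float(in_cs[0]) if in_cs.size else w.offset_s
        cs_span_min = (cs_end - w.onset_s) / 60.0
        n_cs = int(((entries > w.onset_s) & (entries <= cs_end)).sum())
        pre_lo = max(w.pre_onset_s, 0.0)
        pre_span_min = (w.onset_s - pre_lo) / 60.0
        n_pre = int(((entries > pre_lo) & (entries <= w.onset_s)).sum())
        rows.append(
            {
                "subject_id": log.subject_id,
                "session_id": log.session_id,
                "trial": i + 1,
                "cs_type": w.cs_type,
                "cs_rate_per_min": n_cs / cs_span_min if cs_span_min > 0 else 0.0,
                "pre_cs_rate_per_min": n_pre / pre_span_min if pre_span_min > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def feedback_summary(
    logs: list[SessionLog],
    classified_by_session: dict[str, list[ClassifiedPress]],
) -> pd.DataFrame:
    """Per-subject press counts and retrieval proportions by feedback mode.

    One row per (subject, feedback_mode, reinforced status) with the press
    count, the count followed by approach, and their ratio. A session with
    no dispenser activation has zero reinforced presses by definition.
    """
    rows = []
    for log in logs:
        mode = log.condition_tags.get("feedback_mode", "")
        classified = classified_by_session[log.session_id]
        for reinforced in (True, False):
            sel = [c for c in classified if c.reinforced == reinforced]
            n = len(sel)
            n_with = sum(c.with_approach for c in sel)
            rows.append(
                {
                    "subject_id": log.subject_id,
                    "session_id": log.session_id,
                    "feedback_mode": mode,
                    "reinforced": reinforced,
                    "press_count": n,
                    "presses_with_approach": n_with,
                    "proportion_with_approach": (n_with / n) if n else np.nan,
                }
            )
    return pd.DataFrame(rows)
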