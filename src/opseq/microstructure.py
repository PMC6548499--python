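"""Press classification, noncontingent-approach bouts, and peri-event histograms.

The microstructural decomposition treats a lever press followed by a food-cup
entry within a contingency cutoff (2.5 s by default) as a single
press->approach action chunk. Entries are attributed to the *most recent*
press: an entry never credits an earlier press across an intervening one, so
the approach always completes the press that immediately precedes it.
Entries that are not press-contingent are grouped into noncontingent bouts —
a new bout starts only when neither a press nor another entry occurred within
the cutoff beforehand.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events_io import PRESS_TYPES, SessionLog

__all__ = [
    "ClassifiedPress",
    "ApproachBout",
    "Peth",
    "classify_presses",
    "detect_noncontingent_approaches",
    "peri_event_probability",
    "proportion_with_approach",
    "classified_to_frame",
]

DEFAULT_CUTOFF_S = 2.5

_FEEDBACK_TYPES = ("pellet_delivery", "dispenser_cue")

#: Tolerance for "at the press time" feedback attribution (times are stored
#: at millisecond precision, so anything below 1 ms is coincident).
_TIME_EPS = 5e-4


@dataclass(frozen=True)
class ClassifiedPress:
    """One lever press annotated with its microstructural role.

    ``reinforced`` means a pellet delivery or dispenser-cue emission was
    attributed to this press (coincident in time); in cues-only sessions the
    dispenser cue alone marks a press as reinforced. ``with_approach`` means
    a food-cup entry followed within the cutoff with no intervening press;
    ``approach_latency_s`` is the latency of the first such entry.
    ``cs_context`` locates the press relative to cue windows: "CS+", "CS-",
    "preCS+", "preCS-" (the 120 s before an onset) or "none".
    """

    press_time_s: float
    lever: str
    reinforced: bool
    with_approach: bool
    approach_latency_s: float | None = None
    cs_context: str = "none"
    arg: str = ""


@dataclass(frozen=True)
class ApproachBout:
    """A bout of noncontingent food-cup approach.

    Starts >cutoff after the most recent press or entry; subsequent entries
    within the cutoff of the previous one continue the bout.
    """

    start_time_s: float
    n_entries: int
    contingent: bool = False


@dataclass(frozen=True)
class Peth:
    """Peri-event probability histogram.

    ``probability[k]`` is the fraction of alignment events with at least one
    entry onset in bin k, bins half-open ``(edge_k, edge_{k+1}]`` in time
    relative to the alignment event.
    """

    bin_edges_s: np.ndarray
    probability: np.ndarray
    n_events: int

    @property
    def bin_centers_s(self) -> np.ndarray:
        return (self.bin_edges_s[:-1] + self.bin_edges_s[1:]) / 2.0


def _cs_context(log: SessionLog) -> list[tuple[float, float, str]]:
    """Labelled (start, stop, context) intervals from the log's CS events.

    CS windows are closed [onset, offset]; pre-CS windows are the open
    (onset-120, onset) interval before each onset.
    """
    intervals = []
    onset_t, onset_cue = None, None
    for e in log.events:
        if e.event_type == "cs_onset":
            onset_t, onset_cue = e.time_s, e.arg
            intervals.append((max(e.time_s - 120.0, 0.0), e.time_s, "pre" + e.arg))
        elif e.event_type == "cs_offset" and onset_t is not None:
            intervals.append((onset_t, e.time_s, onset_cue))
            onset_t = None
    return intervals


def _context_of(t: float, intervals) -> str:
    for a, b, label in intervals:
        if label.startswith("pre"):
            if a < t < b:
                return label
        elif a <= t <= b:
            return label
    return "none"


def classify_presses(
    log: SessionLog, cutoff_s: float = DEFAULT_CUTOFF_S
) -> list[ClassifiedPress]:
    """Classify every press by reinforcement and contingent-approach status.

    A food-cup entry at time ``t`` is attributed to the most recent press
    ``p`` with ``t - p`` in ``(0, cutoff_s]``; an intervening press captures
    the entry instead. A press is reinforced when a pellet delivery or
    dispenser cue coincides with it. Presses are returned in time order,
    each exactly once.
    """
    if cutoff_s < 0:
        raise ValueError("cutoff_s must be non-negative")
    presses = [e for e in log.events if e.event_type in PRESS_TYPES]
    press_times = [e.time_s for e in presses]
    feedback_times = sorted(log.times(*_FEEDBACK_TYPES))
    entry_times = log.entry_times
    intervals = _cs_context(log)

    # first contingent entry latency per press index
    latency: dict[int, float] = {}
    for t in entry_times:
        i = bisect.bisect_left(press_times, t) - 1  # most recent press strictly before t
        if i >= 0 and 0 < t - press_times[i] <= cutoff_s:
            latency.setdefault(i, t - press_times[i])

    out = []
    for i, p in enumerate(presses):
        j = bisect.bisect_left(feedback_times, p.time_s - _TIME_EPS)
        reinforced = j < len(feedback_times) and abs(feedback_times[j] - p.time_s) <= _TIME_EPS
        out.append(
            ClassifiedPress(
                press_time_s=p.time_s,
                lever=p.event_type,
                reinforced=reinforced,
                with_approach=i in latency,
                approach_latency_s=latency.get(i),
                cs_context=_context_of(p.time_s, intervals),
                arg=p.arg,
            )
        )
    return out


def detect_noncontingent_approaches(
    log: SessionLog, cutoff_s: float = DEFAULT_CUTOFF_S
) -> list[ApproachBout]:
    """Group non-press-contingent entries into noncontingent approach bouts.

    Each entry is exactly one of press-contingent (a press occurred within
    the cutoff before it), a continuation of the current bout (the previous
    entry was within the cutoff), or the start of a new bout. The returned
    bouts partition the noncontingent entries.
    """
    if cutoff_s < 0:
        raise ValueError("cutoff_s must be non-negative")
    press_times = sorted(log.press_times)
    bouts: list[ApproachBout] = []
    prev_entry: float | None = None
    cur_start, cur_n = None, 0
    for t in log.entry_times:
        i = bisect.bisect_left(press_times, t) - 1
        contingent = i >= 0 and 0 < t - press_times[i] <= cutoff_s
        if contingent:
            prev_entry = t
            continue
        if prev_entry is not None and t - prev_entry < cutoff_s and cur_start is not None:
            cur_n += 1
        elif prev_entry is not None and t - prev_entry < cutoff_s:
            # continuation of contingent approach activity: still noncontingent
            # bout bookkeeping requires a start — treat as a new bout anchored
            # at this entry only if the gap rule admits it; otherwise fold into
            # a bout starting here.
            cur_start, cur_n = t, 1
        else:
            if cur_start is not None:
                bouts.append(ApproachBout(cur_start, cur_n))
            cur_start, cur_n = t, 1
        prev_entry = t
    if cur_start is not None:
        bouts.append(ApproachBout(cur_start, cur_n))
    return bouts


def peri_event_probability(
    log: SessionLog,
    align_times,
    window_s: tuple[float, float] = (-5.0, 10.0),
    bin_s: float = 0.5,
) -> Peth:
    """Probability of >=1 food-cup entry per time bin around alignment events.

    ``align_times`` is typically the reinforced or nonreinforced subset of
    press times. Raises on an empty alignment set so that "no events" is
    never conflated with probability zero.
    """
    align = np.asarray(list(align_times), dtype=float)
    if align.size == 0:
        raise ValueError("peri_event_probability needs at least one alignment event")
    lo, hi = window_s
    if not (hi > lo and bin_s > 0):
        raise ValueError("window must be increasing and bin_s positive")
    n_bins = int(round((hi - lo) / bin_s))
    edges = lo + np.arange(n_bins + 1) * bin_s
    entries = np.asarray(log.entry_times, dtype=float)
    hit = np.zeros((align.size, n_bins), dtype=bool)
    for i, t0 in enumerate(align):
        rel = entries - t0
        rel = rel[(rel > lo) & (rel <= hi)]
        if rel.size:
            # bins half-open (edge_k, edge_{k+1}]
            idx = np.ceil((rel - lo) / bin_s).astype(int) - 1
            hit[i, np.clip(idx, 0, n_bins - 1)] = True
    return Peth(edges, hit.mean(axis=0), int(align.size))


def proportion_with_approach(classified, selector=None) -> float | None:
    """Fraction of (selected) presses followed by a contingent approach.

    Returns ``None`` when no press matches the selector — a proportion of an
    empty set is flagged undefined, never reported as zero.
    """
    sel = [c for c in classified if selector is None or selector(c)]
    if not sel:
        return None
    return sum(c.with_approach for c in sel) / len(sel)


def classified_to_frame(classified, subject_id: str = "", session_id: str = "") -> pd.DataFrame:
    """Tidy DataFrame view of a list of classified presses."""
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "session_id": session_id,
            "press_time_s": [c.press_time_s for c in classified],
            "lever": [c.lever for c in classified],
            "arg": [c.arg for c in classified],
            "reinforced": [c.reinforced for c in classified],
            "with_approach": [c.with_approach for c in classified],
            "approach_latency_s": [c.approach_latency_s for c in classified],
            "cs_context": [c.cs_context for c in classified],
        }
    )
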