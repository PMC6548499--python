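"""Virtual-rat session simulator.

Generates synthetic :class:`~opseq.events_io.SessionLog` records with the
statistical structure the microstructure pipeline assumes, under the standard
operant session scripts (random-interval instrumental training and feedback
tests, Pavlovian conditioning, Pavlovian-to-instrumental transfer, and
two-lever reward-devaluation tests).

Generative model
----------------
Press initiations follow a discrete-time Bernoulli approximation of a Poisson
process (hazard ``rate/60 * dt`` per step). Each initiated press is either a
*discrete* press or the start of a *press -> approach action chunk*: after
dispenser feedback the approach probability is ``p_approach_feedback``, and
after a nonreinforced press it is ``p_chunk_nonreinforced``; the chunk's
food-cup entry lags the press by a truncated-exponential latency. A chunk is
treated as an atomic behavioral unit: press initiations that would fall
between a press and its contingent entry are deferred until the entry has
occurred (an animal at the food cup cannot simultaneously press), which
preserves total press counts. Spontaneous (noncontingent) entries form an
independent Poisson background. CS+ presentations act multiplicatively on
the press hazard and on the chunk probability; reward devaluation acts
multiplicatively on press-initiation hazards, separately for discrete and
chunked presses. No learning dynamics or within-session satiety are modeled.

Reinforcement schedules: RI arms after an exponential delay (mean = nominal
interval) from the last reinforcer; RR reinforces each press independently
with probability 1/ratio (CRF = RR 1); RT delivers on a constant-rate time
schedule irrespective of pressing.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import yaml

from .events_io import Event, SessionLog, validate_log

__all__ = [
    "ScheduleSpec",
    "ScheduleState",
    "SimConfig",
    "schedule_step",
    "simulate_instrumental_session",
    "simulate_pavlovian_session",
    "simulate_pit_session",
    "simulate_devaluation_session",
    "simulate_cohort",
    "COHORT_SCRIPTS",
]

_FEEDBACK_MODES = ("food_and_cues", "cues_only", "no_food_or_cues")

#: Minimum spacing (s) enforced between generated food-cup entries.
_MIN_GAP = 0.002


def _round3(t: float) -> float:
    return round(float(t), 3)


# ---------------------------------------------------------------------------
# Reinforcement schedules


@dataclass(frozen=True)
class ScheduleSpec:
    """A schedule of reinforcement.

    kind: "CRF" | "RI" | "RR" | "RT" | "extinction".
    parameter: mean interval in seconds (RI/RT) or ratio (RR); ignored for
    CRF/extinction. reward_cap: maximum reinforcers per session.
    feedback_mode: what a reinforced press produces — pellet plus dispenser
    cues, dispenser cues only, or nothing at all.
    """

    kind: str
    parameter: float = 1.0
    reward_cap: int = 20
    feedback_mode: str = "food_and_cues"

    def __post_init__(self) -> None:
        if self.kind not in ("CRF", "RI", "RR", "RT", "extinction"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.kind in ("RI", "RR", "RT") and not self.parameter > 0:
            raise ValueError(f"{self.kind} schedule needs parameter > 0")
        if self.feedback_mode not in _FEEDBACK_MODES:
            raise ValueError(f"unknown feedback_mode {self.feedback_mode!r}")


@dataclass
class ScheduleState:
    """Mutable per-session schedule state (reward count, RI arming time)."""

    n_rewards: int = 0
    armed_at: float | None = None


def schedule_step(
    spec: ScheduleSpec, state: ScheduleState, press_time: float, rng
) -> tuple[bool, ScheduleState]:
    """Decide whether a press at ``press_time`` is reinforced; update state.

    RI: reinforced iff the arming interval (exponential, mean = parameter,
    timed from the last reinforcer) has elapsed; reinforcement redraws the
    arming delay from the reinforcement time. RR: reinforced with
    probability 1/ratio independently per press. The reward cap is absolute:
    after ``reward_cap`` reinforcers no press is ever reinforced.
    """
    if spec.kind == "extinction" or state.n_rewards >= spec.reward_cap:
        return False, state
    if spec.kind == "RT":
        raise ValueError("RT schedules deliver on time, not on presses")
    if spec.kind == "RI":
        if state.armed_at is None:  # first arming delay drawn from session start
            state.armed_at = float(rng.exponential(spec.parameter))
        if press_time >= state.armed_at:
            state.n_rewards += 1
            state.armed_at = press_time + float(rng.exponential(spec.parameter))
            return True, state
        return False, state
    # CRF / RR
    ratio = 1.0 if spec.kind == "CRF" else float(spec.parameter)
    if rng.random() < 1.0 / ratio:
        state.n_rewards += 1
        return True, state
    return False, state


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of the virtual rat.

    Rates are per minute, latencies in seconds, multipliers dimensionless.
    Defaults are chosen for qualitative realism of a moderately trained rat
    on sparse-reward schedules: ~8 presses/min with sporadic retrieval after
    nonreinforced presses (p = 0.1) and near-certain retrieval after
    dispenser feedback (p = 0.9) at sub-second latency, a low spontaneous
    entry background, a three-fold CS+ gain on pressing and chunking, and
    devaluation suppressing discrete presses five-fold but chunked presses
    only weakly.
    """

    press_rate_per_min: float = 8.0
    p_chunk_nonreinforced: float = 0.10
    p_approach_feedback: float = 0.90
    approach_latency_mean_s: float = 0.8
    approach_latency_max_s: float = 2.5
    background_approach_rate_per_min: float = 0.5
    cs_press_multiplier: float = 3.0
    cs_chunk_multiplier: float = 3.0
    cs_entry_multiplier: float = 3.0
    deval_press_multiplier_discrete: float = 0.2
    deval_press_multiplier_chunk: float = 0.8
    time_step_s: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_chunk_nonreinforced", "p_approach_feedback"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "press_rate_per_min",
            "background_approach_rate_per_min",
            "cs_press_multiplier",
            "cs_chunk_multiplier",
            "cs_entry_multiplier",
            "deval_press_multiplier_discrete",
            "deval_press_multiplier_chunk",
            "approach_latency_mean_s",
            "approach_latency_max_s",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.time_step_s > 0:
            raise ValueError("time_step_s must be > 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


# ---------------------------------------------------------------------------
# Low-level draws


def _candidate_press_times(rng, rate_per_step: np.ndarray, dt: float) -> np.ndarray:
    """Bernoulli-per-step press initiations; returns candidate times."""
    hits = rng.random(rate_per_step.size) < rate_per_step
    return (np.flatnonzero(hits) + 1) * dt


def _truncexp(rng, mean: float, maxv: float, size: int | None = None) -> np.ndarray:
    """Exponential(mean) truncated to (0, maxv] by inverse-CDF sampling."""
    u = rng.random(size)
    cdf_max = -np.expm1(-maxv / mean)
    return -mean * np.log1p(-u * cdf_max)


def _poisson_times(rng, rate_per_s: float, t0: float, t1: float) -> np.ndarray:
    if rate_per_s <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate_per_s * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, n))


def _entry_exit_events(rng, entry_times, t_end: float) -> list[Event]:
    """Turn raw entry times into alternating entry/exit events.

    Entries closer than the minimum gap are dropped (a single beam break);
    exits are placed after an exponential occupancy (mean 1 s), clipped to
    stay before the next entry and the session end.
    """
    times = sorted(_round3(t) for t in entry_times if 0 < t < t_end - _MIN_GAP)
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= 2 * _MIN_GAP:
            kept.append(t)
    events: list[Event] = []
    for i, t in enumerate(kept):
        dur = max(float(rng.exponential(1.0)), 0.05)
        limit = kept[i + 1] - _MIN_GAP / 2 if i + 1 < len(kept) else t_end
        exit_t = _round3(min(t + dur, limit, t_end))
        exit_t = max(exit_t, _round3(t + 0.001))
        events.append(Event(t, "foodcup_entry"))
        events.append(Event(exit_t, "foodcup_exit"))
    return events


def _finalize(
    subject_id, session_id, session_type, duration, events, tags
) -> SessionLog:
    events = [e for e in events if e.time_s <= duration]
    events.append(Event(_round3(duration), "session_end"))
    log = SessionLog(
        subject_id=subject_id,
        session_id=session_id,
        session_type=session_type,
        duration_s=_round3(duration),
        events=events,
        condition_tags=dict(tags or {}),
    ).sorted()
    return validate_log(log)


# ---------------------------------------------------------------------------
# Session scripts


def _press_scan(
    cfg: SimConfig,
    rng,
    candidates: np.ndarray,
    duration: float,
    decide,
) -> tuple[list[Event], list[float], float]:
    """Shared sequential press scan with atomic-chunk deferral.

    ``decide(press_time)`` returns ``(events_at_press, approach_p)`` where
    ``events_at_press`` are feedback events to emit at the press time and
    ``approach_p`` the probability of a contingent approach. Returns the
    press/feedback events, the contingent entry times, and the time at which
    the session was truncated (== duration unless a cap fired).
    """
    events: list[Event] = []
    entries: list[float] = []
    next_free = 0.0
    prev_press = -1.0
    for t in candidates:
        t_eff = _round3(max(float(t), next_free))
        if t_eff <= prev_press:
            t_eff = _round3(prev_press + 0.01)
        if t_eff >= duration:
            break
        feedback, approach_p, lever, arg = decide(t_eff)
        events.append(Event(t_eff, lever, arg))
        for ev in feedback:
            events.append(ev)
        prev_press = t_eff
        if approach_p > 0 and rng.random() < approach_p:
            lat = max(float(_truncexp(rng, cfg.approach_latency_mean_s,
                                      cfg.approach_latency_max_s)), 0.001)
            entry_t = _round3(t_eff + lat)
            entries.append(entry_t)
            next_free = entry_t + 0.01
    return events, entries, duration


def simulate_instrumental_session(
    cfg: SimConfig,
    spec: ScheduleSpec,
    duration_s: float = 1800.0,
    *,
    rng=None,
    subject_id: str = "rat00",
    session_id: str = "instrumental",
    session_type: str = "instrumental",
    lever: str = "press_right",
    condition_tags: dict | None = None,
) -> SessionLog:
    """Simulate a single-lever instrumental (or feedback-test) session.

    The session truncates at ``duration_s`` or at the schedule's reward cap,
    whichever comes first (a 3 s grace period after the capping reward lets
    the final retrieval land inside the log).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    dt = cfg.time_step_s
    n_steps = int(round(duration_s / dt))
    rate = np.full(n_steps, cfg.press_rate_per_min / 60.0 * dt)
    candidates = _candidate_press_times(rng, rate, dt)

    state = ScheduleState()
    emits_feedback = spec.feedback_mode != "no_food_or_cues"
    cap_time = [None]

    def decide(t):
        reinforced, _ = schedule_step(spec, state, t, rng)
        feedback = []
        if reinforced and emits_feedback:
            if spec.feedback_mode == "food_and_cues":
                feedback.append(Event(t, "pellet_delivery"))
            feedback.append(Event(t, "dispenser_cue"))
            if state.n_rewards >= spec.reward_cap and cap_time[0] is None:
                cap_time[0] = t
            return feedback, cfg.p_approach_feedback, lever, ""
        return feedback, cfg.p_chunk_nonreinforced, lever, ""

    events, entries, _ = _press_scan(cfg, rng, candidates, duration_s, decide)
    t_end = duration_s if cap_time[0] is None else min(duration_s, cap_time[0] + 3.0)
    events = [e for e in events if e.time_s <= t_end]
    entries = [t for t in entries if t <= t_end]

    bg = _poisson_times(rng, cfg.background_approach_rate_per_min / 60.0, 0.0, t_end)
    events.extend(_entry_exit_events(rng, list(entries) + list(bg), t_end))
    return _finalize(subject_id, session_id, session_type, t_end, events,
                     condition_tags)


def simulate_pavlovian_session(
    cfg: SimConfig,
    n_trials: int = 6,
    reinforced: bool = True,
    *,
    rng=None,
    subject_id: str = "rat00",
    session_id: str = "pavlovian",
    condition_tags: dict | None = None,
) -> SessionLog:
    """Simulate a Pavlovian conditioning session (no lever available).

    ``n_trials`` 2-min cue presentations with 4-6 min onset-to-onset
    spacing. Reinforced (CS+) trials deliver pellets on a random-time 30 s
    schedule (Poisson, rate 1/30 per s, ~4 pellets per trial); each pellet
    triggers a retrieval entry with probability ``p_approach_feedback``.
    Entries otherwise follow the background rate, multiplied by
    ``cs_entry_multiplier`` during CS+ presentations (conditioned approach).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    cue = "CS+" if reinforced else "CS-"
    onsets = []
    t = float(rng.uniform(240.0, 360.0))
    for _ in range(n_trials):
        onsets.append(_round3(t))
        t += float(rng.uniform(240.0, 360.0))
    duration = _round3(onsets[-1] + 120.0 + 180.0)

    events: list[Event] = []
    entries: list[float] = []
    bg_rate = cfg.background_approach_rate_per_min / 60.0
    prev_off = 0.0
    for onset in onsets:
        offset = _round3(onset + 120.0)
        events.append(Event(onset, "cs_onset", cue))
        events.append(Event(offset, "cs_offset", cue))
        entries.extend(_poisson_times(rng, bg_rate, prev_off, onset))
        cs_rate = bg_rate * (cfg.cs_entry_multiplier if reinforced else 1.0)
        entries.extend(_poisson_times(rng, cs_rate, onset, offset))
        if reinforced:
            for pt in _poisson_times(rng, 1.0 / 30.0, onset, offset):
                pt = _round3(pt)
                events.append(Event(pt, "pellet_delivery"))
                if rng.random() < cfg.p_approach_feedback:
                    lat = max(float(_truncexp(rng, cfg.approach_latency_mean_s,
                                              cfg.approach_latency_max_s)), 0.001)
                    entries.append(pt + lat)
        prev_off = offset
    entries.extend(_poisson_times(rng, bg_rate, prev_off, duration))
    events.extend(_entry_exit_events(rng, entries, duration))
    return _finalize(subject_id, session_id, "pavlovian", duration, events,
                     condition_tags)


def _pit_trial_order(rng) -> list[str]:
    """Seeded pseudorandom order of 4 CS+ / 4 CS- with <=2 consecutive repeats."""
    trials = np.array(["CS+"] * 4 + ["CS-"] * 4)
    while True:
        order = list(rng.permutation(trials))
        if all(
            not (order[i] == order[i + 1] == order[i + 2])
            for i in range(len(order) - 2)
        ):
            return order


def simulate_pit_session(
    cfg: SimConfig,
    *,
    rng=None,
    subject_id: str = "rat00",
    session_id: str = "pit",
    lever: str = "press_right",
    condition_tags: dict | None = None,
) -> SessionLog:
    """Simulate a Pavlovian-to-instrumental transfer test.

    480 s of extinction lead-in, then 8 noncontingent 2-min cue trials
    (4 CS+, 4 CS-, pseudorandom order, 180 s fixed ITI). No press ever
    produces food or cues. During CS+ the press hazard is multiplied by
    ``cs_press_multiplier`` and the chunk probability by
    ``cs_chunk_multiplier`` (capped at 1); CS- leaves both unchanged.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    dt = cfg.time_step_s
    order = _pit_trial_order(rng)
    windows = []  # (cue, onset, offset)
    t = 480.0
    for cue in order:
        windows.append((cue, t, t + 120.0))
        t += 300.0
    duration = windows[-1][2] + 180.0

    n_steps = int(round(duration / dt))
    step_times = (np.arange(n_steps) + 1) * dt
    base = cfg.press_rate_per_min / 60.0 * dt
    rate = np.full(n_steps, base)
    plus_windows = [(a, b) for cue, a, b in windows if cue == "CS+"]
    for a, b in plus_windows:
        rate[(step_times > a) & (step_times <= b)] = base * cfg.cs_press_multiplier
    candidates = _candidate_press_times(rng, rate, dt)

    def in_cs_plus(t):
        return any(a <= t <= b for a, b in plus_windows)

    def decide(t):
        p = cfg.p_chunk_nonreinforced
        if in_cs_plus(t):
            p = min(p * cfg.cs_chunk_multiplier, 1.0)
        return [], p, lever, ""

    events, entries, _ = _press_scan(cfg, rng, candidates, duration, decide)
    for cue, a, b in windows:
        events.append(Event(_round3(a), "cs_onset", cue))
        events.append(Event(_round3(b), "cs_offset", cue))
    bg = _poisson_times(rng, cfg.background_approach_rate_per_min / 60.0,
                        0.0, duration)
    events.extend(_entry_exit_events(rng, list(entries) + list(bg), duration))
    return _finalize(subject_id, session_id, "pit_test", duration, events,
                     condition_tags)


def simulate_devaluation_session(
    cfg: SimConfig,
    devalued_side: str = "left",
    *,
    rng=None,
    subject_id: str = "rat00",
    session_id: str = "deval",
    condition_tags: dict | None = None,
) -> SessionLog:
    """Simulate a two-lever reward-devaluation test.

    5-min nonreinforced phase followed by a 15-min reinforced phase (per
    lever: CRF for the first five rewards, then RR-20). During the
    nonreinforced phase the devalued lever's press-initiation hazard is
    scaled by ``deval_press_multiplier_discrete`` for discrete presses and
    ``deval_press_multiplier_chunk`` for chunked presses; lever identities
    are tagged ``valued`` / ``devalued`` in the event ``arg``.
    """
    if devalued_side not in ("left", "right"):
        raise ValueError("devalued_side must be 'left' or 'right'")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    dt = cfg.time_step_s
    ext_end, duration = 300.0, 1200.0
    base = cfg.press_rate_per_min / 60.0 * dt  # per lever
    p_c = cfg.p_chunk_nonreinforced

    # Candidate streams: (lever_side, intended_type) with phase-specific rates.
    candidates: list[tuple[float, str, str]] = []
    n_ext = int(round(ext_end / dt))
    n_reinf = int(round((duration - ext_end) / dt))
    for side in ("left", "right"):
        devalued = side == devalued_side
        m_c = cfg.deval_press_multiplier_chunk if devalued else 1.0
        m_d = cfg.deval_press_multiplier_discrete if devalued else 1.0
        for kind, r in (("chunk", base * p_c * m_c), ("discrete", base * (1 - p_c) * m_d)):
            for t in _candidate_press_times(rng, np.full(n_ext, r), dt):
                candidates.append((float(t), side, kind))
        # reinforced phase: unsuppressed hazard, chunking decided by feedback
        for t in _candidate_press_times(rng, np.full(n_reinf, base), dt):
            candidates.append((ext_end + float(t), side, "schedule"))
    candidates.sort()

    states = {"left": ScheduleState(), "right": ScheduleState()}
    rr20 = ScheduleSpec("RR", 20.0, reward_cap=10**9)

    events: list[Event] = []
    entries: list[float] = []
    next_free = 0.0
    prev_press = -1.0
    for t, side, kind in candidates:
        t_eff = _round3(max(t, next_free))
        if t_eff <= prev_press:
            t_eff = _round3(prev_press + 0.01)
        if t_eff >= duration:
            continue
        lever = f"press_{side}"
        arg = "devalued" if side == devalued_side else "valued"
        approach_p = 0.0
        if kind == "chunk":
            approach_p = 1.0
        elif kind == "schedule" and t_eff > ext_end:
            st = states[side]
            if st.n_rewards < 5:  # CRF for the first five rewards per lever
                reinforced = True
                st.n_rewards += 1
            else:
                reinforced, _ = schedule_step(rr20, st, t_eff, rng)
            if reinforced:
                events.append(Event(t_eff, "pellet_delivery"))
                events.append(Event(t_eff, "dispenser_cue"))
                approach_p = cfg.p_approach_feedback
            else:
                approach_p = p_c
        events.append(Event(t_eff, lever, arg))
        prev_press = t_eff
        if approach_p > 0 and rng.random() < approach_p:
            lat = max(float(_truncexp(rng, cfg.approach_latency_mean_s,
                                      cfg.approach_latency_max_s)), 0.001)
            entry_t = _round3(t_eff + lat)
            entries.append(entry_t)
            next_free = entry_t + 0.01
    bg = _poisson_times(rng, cfg.background_approach_rate_per_min / 60.0,
                        0.0, duration)
    events.extend(_entry_exit_events(rng, entries + list(bg), duration))
    return _finalize(subject_id, session_id, "devaluation_test", duration,
                     events, condition_tags)


# ---------------------------------------------------------------------------
# Cohorts

COHORT_SCRIPTS = ("exp1_feedback", "exp2_pit", "exp3_pit", "exp4_devaluation")


def _subject_rng(seed: int, subject: int, session: int):
    """Independent, reproducible substream for (seed, subject, session)."""
    return np.random.default_rng([int(seed), int(subject), int(session)])


def simulate_cohort(
    cfg: SimConfig,
    n_subjects: int,
    experiment_script: str,
    seed: int | None = None,
    *,
    cno_cfg: SimConfig | None = None,
) -> list[SessionLog]:
    """Simulate a full cohort under one of the canned experiment scripts.

    Deterministic given ``seed`` (defaults to ``cfg.seed``); each
    (subject, session) pair draws from an independent substream. Drug
    effects are represented only by supplying a second configuration
    (``cno_cfg``) used for CNO-tagged sessions.

    Scripts: ``exp1_feedback`` — three 30-min RI-60s feedback tests per
    subject (food+cues, cues only, no food or cues); ``exp2_pit`` — one
    Pavlovian session plus one PIT test; ``exp3_pit`` — four PIT tests
    (2 vehicle, 2 CNO); ``exp4_devaluation`` — four devaluation tests
    crossing drug with devalued lever.
    """
    if experiment_script not in COHORT_SCRIPTS:
        raise ValueError(f"unknown experiment script {experiment_script!r}")
    seed = cfg.seed if seed is None else seed
    cno = cno_cfg or cfg
    logs: list[SessionLog] = []
    for i in range(n_subjects):
        sid = f"rat{i:02d}"
        if experiment_script == "exp1_feedback":
            for j, mode in enumerate(_FEEDBACK_MODES):
                kind = "extinction" if mode == "no_food_or_cues" else "RI"
                spec = ScheduleSpec(kind, 60.0, reward_cap=20, feedback_mode=mode)
                logs.append(
                    simulate_instrumental_session(
                        cfg, spec, 1800.0, rng=_subject_rng(seed, i, j),
                        subject_id=sid, session_id=f"{sid}_{mode}",
                        session_type="feedback_test",
                        condition_tags={"feedback_mode": mode},
                    )
                )
        elif experiment_script == "exp2_pit":
            logs.append(
                simulate_pavlovian_session(
                    cfg, 6, True, rng=_subject_rng(seed, i, 0),
                    subject_id=sid, session_id=f"{sid}_pav",
                )
            )
            logs.append(
                simulate_pit_session(
                    cfg, rng=_subject_rng(seed, i, 1), subject_id=sid,
                    session_id=f"{sid}_pit", condition_tags={"drug": "vehicle"},
                )
            )
        elif experiment_script == "exp3_pit":
            for j, drug in enumerate(["vehicle", "vehicle", "cno", "cno"]):
                c = cfg if drug == "vehicle" else cno
                logs.append(
                    simulate_pit_session(
                        c, rng=_subject_rng(seed, i, j), subject_id=sid,
                        session_id=f"{sid}_pit_{drug}_{j % 2 + 1}",
                        condition_tags={"drug": drug, "test_index": str(j % 2 + 1)},
                    )
                )
        else:  # exp4_devaluation
            combos = [("vehicle", "left"), ("vehicle", "right"),
                      ("cno", "left"), ("cno", "right")]
            for j, (drug, side) in enumerate(combos):
                c = cfg if drug == "vehicle" else cno
                logs.append(
                    simulate_devaluation_session(
                        c, side, rng=_subject_rng(seed, i, j), subject_id=sid,
                        session_id=f"{sid}_deval_{drug}_{side}",
                        condition_tags={"drug": drug, "devalued_outcome": side},
                    )
                )
    return logs
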