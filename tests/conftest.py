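import numpy as np
import pytest
from hypothesis import settings

from opseq.events_io import Event, SessionLog

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_log(
    press_times=(),
    entry_times=(),
    *,
    pellet_times=(),
    dispenser_times=(),
    cs_windows=(),
    exit_times=None,
    duration=None,
    session_type="instrumental",
    subject_id="rat00",
    session_id="s1",
    press_type="press_right",
    press_args=None,
) -> SessionLog:
    """Build a valid SessionLog from bare event times.

    Food-cup exits are auto-interleaved midway between consecutive entries
    unless given explicitly; cs_windows are (cue, onset, offset) triples.
    """
    events = [
        Event(t, press_type, (press_args or {}).get(i, ""))
        for i, t in enumerate(press_times)
    ]
    events += [Event(t, "pellet_delivery") for t in pellet_times]
    events += [Event(t, "dispenser_cue") for t in dispenser_times]
    entries = sorted(entry_times)
    events += [Event(t, "foodcup_entry") for t in entries]
    all_times = [e.time_s for e in events] + [
        b for _, _, b in cs_windows
    ]
    dur = duration if duration is not None else (max(all_times, default=0.0) + 10.0)
    if exit_times is None:
        exit_times = []
        for i, t in enumerate(entries):
            nxt = entries[i + 1] if i + 1 < len(entries) else dur
            exit_times.append(round(min(t + 0.4, (t + nxt) / 2.0), 3))
    events += [Event(t, "foodcup_exit") for t in exit_times]
    for cue, a, b in cs_windows:
        events.append(Event(a, "cs_onset", cue))
        events.append(Event(b, "cs_offset", cue))
    events.append(Event(dur, "session_end"))
    return SessionLog(
        subject_id=subject_id,
        session_id=session_id,
        session_type=session_type,
        duration_s=dur,
        events=events,
    ).sorted()


def random_log(rng: np.random.Generator, n_events: int = 100) -> SessionLog:
    """Random valid log on a millisecond grid for property testing."""
    duration = float(rng.integers(60, 1200))
    n_press = int(rng.integers(0, max(n_events // 2, 1)))
    n_entry = max(n_events - n_press, 0) // 2
    press = np.round(np.sort(rng.uniform(0, duration, n_press)), 3)
    press = np.unique(press)
    entries = np.round(np.sort(rng.uniform(0, duration, n_entry)), 3)
    entries = np.unique(entries)
    entries = entries[np.concatenate(([True], np.diff(entries) > 0.002))]
    # reinforce a random subset of presses with coincident feedback
    reinforced = press[rng.random(press.size) < 0.25]
    return make_log(
        press_times=press.tolist(),
        entry_times=entries.tolist(),
        pellet_times=reinforced.tolist(),
        dispenser_times=reinforced.tolist(),
        duration=duration,
    )


@pytest.fixture(scope="session")
def base_rng():
    return np.random.default_rng(20260919)
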