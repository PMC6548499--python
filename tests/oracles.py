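"""Independent brute-force oracles for the microstructure rules.

These re-derive press classification and bout membership by exhaustive
examination of every (press, entry) pair, independently of the package's
single-pass implementations.
"""

import numpy as np


def brute_force_classify(press_times, entry_times, cutoff):
    """Exhaustive O(n^2) press classification.

    For every (press, entry) pair, the entry is attributable to the press iff
    0 < entry - press <= cutoff and no other press lies strictly between.
    Returns (with_approach: list[bool], latency: list[float | None]).
    """
    press = np.asarray(press_times, float)
    entries = np.asarray(entry_times, float)
    with_approach = [False] * press.size
    latency = [None] * press.size
    for i, p in enumerate(press):
        best = None
        # entries with 0 < t - p <= cutoff (all other pairs trivially fail)
        for t in entries[(entries > p) & (entries <= p + cutoff)]:
            if not np.any((press > p) & (press < t)):
                lat = t - p
                if best is None or lat < best:
                    best = lat
        if best is not None:
            with_approach[i] = True
            latency[i] = best
    return with_approach, latency


def brute_force_bouts(press_times, entry_times, cutoff):
    """Exhaustive bout detection: returns (bout_list, n_contingent_entries).

    An entry is press-contingent iff some press precedes it within the
    cutoff. Otherwise it continues the open bout when the previous entry was
    strictly within the cutoff, else starts a new bout.
    """
    press = np.asarray(press_times, float)
    bouts = []
    cur = None
    prev_entry = None
    n_contingent = 0
    for t in sorted(entry_times):
        if bool(np.any((press < t) & (t - press <= cutoff))):
            n_contingent += 1
            prev_entry = t
            continue
        new_bout = cur is None or prev_entry is None or t - prev_entry >= cutoff
        if new_bout:
            if cur is not None:
                bouts.append(tuple(cur))
            cur = [t, 1]
        else:
            cur[1] += 1
        prev_entry = t
    if cur is not None:
        bouts.append(tuple(cur))
    return bouts, n_contingent
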