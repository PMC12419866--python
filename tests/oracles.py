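"""Independent brute-force oracles, coded separately from the package.

Each oracle restates the measurement rule in the most direct form possible
(all interval-bin pairs; explicit successive-pair loops) and is used to
cross-check the vectorized implementations on randomized instances.
"""

import numpy as np
import pandas as pd


def brute_force_bin_counts(intervals: pd.DataFrame, bin_width: int, date) -> np.ndarray:
    """Per-bin active-interval counts by checking every interval-bin pair.

    An interval is active in bin [b, b+w) when it covers any instant of the
    bin: for a positive-length interval treated as [start, end), that is
    start < b+w and end > b; a zero-length interval is active in the bin
    containing its timestamp.
    """
    date = pd.Timestamp(date).normalize()
    n_bins = 1440 // bin_width
    counts = np.zeros(n_bins, dtype=int)
    w = 60 * bin_width
    for _, row in intervals.iterrows():
        s = (row["start"] - date).total_seconds()
        e = (row["end"] - date).total_seconds()
        for b in range(n_bins):
            lo, hi = b * w, (b + 1) * w
            if s == e:
                active = lo <= s < hi
            else:
                active = s < hi and e > lo
            if active:
                counts[b] += 1
    return counts


def sweep_max_active(intervals: pd.DataFrame) -> int:
    """Continuous-time maximum of simultaneously active intervals.

    Event-boundary sweep: +1 at starts, -1 just after ends (closed at the
    right endpoint so zero-length intervals count at their instant).
    """
    events = []
    for _, row in intervals.iterrows():
        events.append((row["start"].value, 0, +1))
        events.append((row["end"].value, 1, -1))  # after starts at same instant
    events.sort()
    best = cur = 0
    for _, _, delta in events:
        cur += delta
        best = max(best, cur)
    return best


def brute_force_ehr_time(events: pd.DataFrame, threshold_min: float = 5.0) -> float:
    """Successive-gap sum in minutes, dropping gaps above the threshold."""
    ts = sorted(events["timestamp"].tolist())
    total = 0.0
    for a, b in zip(ts, ts[1:]):
        gap = (b - a).total_seconds()
        if gap <= threshold_min * 60.0:
            total += gap
    return total / 60.0


def brute_force_switches(events: pd.DataFrame, threshold_min: float = 5.0) -> int:
    """Drop patient-less rows, then count qualifying adjacent differing pairs."""
    day = events[events["patient_id"].notna()].sort_values("timestamp", kind="stable")
    rows = list(day.itertuples(index=False))
    count = 0
    for a, b in zip(rows, rows[1:]):
        gap = (b.timestamp - a.timestamp).total_seconds()
        if a.patient_id != b.patient_id and gap <= threshold_min * 60.0:
            count += 1
    return count
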