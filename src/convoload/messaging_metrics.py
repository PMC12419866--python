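"""Concurrency metrics for secure-messaging conversation threads.

A conversation thread is considered *active* from the clinician's first to
last message activity (send or read) in that thread within a calendar day.
Conversational multitasking is quantified by binning the day (default
1-minute bins) and counting, per bin, the number of active threads.  A lone
active thread counts as zero concurrency; the day's exposure category is
derived from the maximum number of simultaneously active threads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440
VALID_BIN_WIDTHS = (1, 2, 5)

MESSAGE_COLUMNS = ["conversation_id", "clinician_id", "direction", "timestamp"]
DIRECTIONS = frozenset({"sent", "read"})


class ExposureCategory(str, Enum):
    """Daily exposure group from the maximum number of concurrent threads.

    ``NONE`` means no two threads ever overlapped (max active <= 1);
    ``TWO``/``THREE`` mean the maximum was exactly 2/3 simultaneously
    active threads; ``FOUR_PLUS`` means 4 or more.
    """

    NONE = "NONE"
    TWO = "TWO"
    THREE = "THREE"
    FOUR_PLUS = "FOUR_PLUS"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Ordering used for "category at coarser bin width >= category at finer".
CATEGORY_ORDER = {
    ExposureCategory.NONE: 0,
    ExposureCategory.TWO: 1,
    ExposureCategory.THREE: 2,
    ExposureCategory.FOUR_PLUS: 3,
}


@dataclass(frozen=True)
class ConcurrencyTrace:
    """Per-bin active-thread counts for one clinician-day.

    ``n_active`` holds, for every bin of the day (``1440 / bin_width``
    entries aligned to midnight), the number of threads active in that
    bin.  ``concurrency`` applies the lone-thread-is-zero rule.
    """

    clinician_id: str
    date: pd.Timestamp
    bin_width: int
    n_active: np.ndarray = field(repr=False)

    @property
    def concurrency(self) -> np.ndarray:
        return np.where(self.n_active >= 2, self.n_active, 0)

    @property
    def bin_starts(self) -> pd.DatetimeIndex:
        start = pd.Timestamp(self.date)
        return pd.date_range(start, periods=len(self.n_active), freq=f"{self.bin_width}min")

    def to_frame(self, trim: bool = True) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "bin_start": self.bin_starts,
                "n_active": self.n_active,
                "concurrency": self.concurrency,
            }
        )
        if trim:
            out = out[out["n_active"] > 0].reset_index(drop=True)
        return out


@dataclass(frozen=True)
class MessagingSummary:
    """Daily messaging covariates and the exposure category."""

    clinician_id: str
    date: pd.Timestamp
    msg_volume: int
    total_msg_time: float  # minutes, union of active intervals
    pct_concurrent_time: float  # 0-100
    max_concurrent: int
    category: ExposureCategory


def _validate_bin_width(bin_width: int) -> None:
    if bin_width not in VALID_BIN_WIDTHS:
        raise ValueError(f"bin_width must be one of {VALID_BIN_WIDTHS}, got {bin_width!r}")


def parse_message_events(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a raw messaging-metadata table.

    Timestamps are parsed to timezone-naive datetimes; an unparseable
    timestamp or an unknown direction raises with the offending row index.
    """
    missing = [c for c in MESSAGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"message table missing columns: {missing}")
    out = df.copy()
    ts = pd.to_datetime(out["timestamp"], errors="coerce")
    bad = ts.isna() & out["timestamp"].notna()
    if bad.any():
        raise ValueError(f"unparseable timestamp at row index {bad.idxmax()}")
    if ts.isna().any():
        raise ValueError(f"missing timestamp at row index {ts.isna().idxmax()}")
    out["timestamp"] = ts
    bad_dir = ~out["direction"].isin(DIRECTIONS)
    if bad_dir.any():
        raise ValueError(
            f"direction must be one of {sorted(DIRECTIONS)}; "
            f"bad value at row index {bad_dir.idxmax()}"
        )
    return out


def conversation_intervals(events: pd.DataFrame, date) -> pd.DataFrame:
    """Active interval per conversation thread for one clinician-day.

    Events outside ``date`` are ignored (threads are clipped to calendar
    days; a thread spanning midnight yields a separate interval on each
    day).  A single-event thread yields a zero-length interval.

    Returns a frame with columns ``conversation_id, clinician_id, date,
    start, end``.
    """
    date = pd.Timestamp(date).normalize()
    if events.empty:
        return pd.DataFrame(
            columns=["conversation_id", "clinician_id", "date", "start", "end"]
        )
    clinicians = events["clinician_id"].unique()
    if len(clinicians) > 1:
        raise ValueError(f"events must belong to one clinician, got {list(clinicians)}")
    ts = events["timestamp"]
    day = events[(ts >= date) & (ts < date + pd.Timedelta(days=1))]
    if day.empty:
        return pd.DataFrame(
            columns=["conversation_id", "clinician_id", "date", "start", "end"]
        )
    grouped = day.groupby("conversation_id", sort=True)["timestamp"].agg(["min", "max"])
    out = grouped.reset_index().rename(columns={"min": "start", "max": "end"})
    out.insert(1, "clinician_id", clinicians[0])
    out.insert(2, "date", date)
    return out


def _interval_bins(start_sec: np.ndarray, end_sec: np.ndarray, bin_width: int):
    """Map second-resolution intervals to half-open bin index ranges.

    Intervals are treated as half-open ``[start, end)`` so that a thread
    ending exactly on a bin boundary is not active in that bin; a
    zero-length interval (single-message thread) is active in the single
    bin containing its timestamp.
    """
    w = 60 * bin_width
    first = start_sec // w
    last = np.where(end_sec > start_sec, -(-end_sec // w), first + 1)  # ceil
    return first.astype(int), np.minimum(last, MINUTES_PER_DAY // bin_width).astype(int)


def concurrency_trace(
    intervals: pd.DataFrame,
    bin_width: int = 1,
    clinician_id: str | None = None,
    date=None,
) -> ConcurrencyTrace:
    """Per-bin count of active conversation threads for one clinician-day.

    Bins are half-open ``[t, t + bin_width)`` aligned to midnight.  An
    empty interval set yields an all-zero (valid, empty-union) trace.
    """
    _validate_bin_width(bin_width)
    n_bins = MINUTES_PER_DAY // bin_width
    counts = np.zeros(n_bins, dtype=np.int64)
    if not intervals.empty:
        uniq_c = intervals["clinician_id"].unique()
        uniq_d = pd.to_datetime(intervals["date"]).unique()
        if len(uniq_c) > 1 or len(uniq_d) > 1:
            raise ValueError("intervals must come from a single clinician-date")
        clinician_id = clinician_id or uniq_c[0]
        date = pd.Timestamp(date if date is not None else uniq_d[0]).normalize()
        start_sec = (
            (pd.to_datetime(intervals["start"]) - date).dt.total_seconds().to_numpy()
        )
        end_sec = (pd.to_datetime(intervals["end"]) - date).dt.total_seconds().to_numpy()
        if (start_sec < 0).any() or (end_sec >= 86400 + 1).any():
            raise ValueError("interval outside the stated date")
        first, last = _interval_bins(start_sec, end_sec, bin_width)
        np.add.at(counts, np.concatenate([np.arange(f, l) for f, l in zip(first, last)]), 1)
    else:
        date = pd.Timestamp(date if date is not None else 0).normalize()
    return ConcurrencyTrace(
        clinician_id=clinician_id or "", date=date, bin_width=bin_width, n_active=counts
    )


def max_concurrent(trace: ConcurrencyTrace) -> int:
    """Day maximum of simultaneously active threads (0 for an empty trace)."""
    if len(trace.n_active) == 0:
        return 0
    return int(trace.n_active.max())


def categorize(max_concurrent: int) -> ExposureCategory:
    """Map the day's maximum active-thread count to an exposure group."""
    if max_concurrent < 0:
        raise ValueError("max_concurrent must be >= 0")
    if max_concurrent <= 1:
        return ExposureCategory.NONE
    if max_concurrent == 2:
        return ExposureCategory.TWO
    if max_concurrent == 3:
        return ExposureCategory.THREE
    return ExposureCategory.FOUR_PLUS


def messaging_summary(
    events: pd.DataFrame, date, bin_width: int = 1
) -> MessagingSummary:
    """Daily messaging summary for one clinician.

    ``msg_volume`` counts all sent + read activities on the date;
    ``total_msg_time`` is the measure (in minutes) of the union of active
    intervals; ``pct_concurrent_time`` divides minutes with >= 2 active
    threads by the union time (defined as 0 for a day with no messaging).
    """
    _validate_bin_width(bin_width)
    date = pd.Timestamp(date).normalize()
    clinician_id = events["clinician_id"].iloc[0] if len(events) else ""
    intervals = conversation_intervals(events, date)
    trace = concurrency_trace(intervals, bin_width, clinician_id=clinician_id, date=date)
    active_bins = int((trace.n_active >= 1).sum())
    concurrent_bins = int((trace.n_active >= 2).sum())
    total_time = float(active_bins * bin_width)
    pct = 100.0 * concurrent_bins / active_bins if active_bins else 0.0
    if events.empty:
        volume = 0
    else:
        ts = events["timestamp"]
        volume = int(((ts >= date) & (ts < date + pd.Timedelta(days=1))).sum())
    mc = max_concurrent(trace)
    return MessagingSummary(
        clinician_id=clinician_id,
        date=date,
        msg_volume=volume,
        total_msg_time=total_time,
        pct_concurrent_time=pct,
        max_concurrent=mc,
        category=categorize(mc),
    )


def summarize_messages(messages: pd.DataFrame, bin_width: int = 1) -> pd.DataFrame:
    """Per clinician-day messaging summaries for a full messaging table."""
    messages = parse_message_events(messages)
    rows = []
    dates = messages["timestamp"].dt.normalize()
    for (clin, date), grp in messages.groupby([messages["clinician_id"], dates], sort=True):
        s = messaging_summary(grp, date, bin_width)
        rows.append(
            {
                "clinician_id": clin,
                "date": date,
                "msg_volume": s.msg_volume,
                "total_msg_time": s.total_msg_time,
                "pct_concurrent_time": s.pct_concurrent_time,
                "max_concurrent": s.max_concurrent,
                "exposure": s.category.value,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "clinician_id",
            "date",
            "msg_volume",
            "total_msg_time",
            "pct_concurrent_time",
            "max_concurrent",
            "exposure",
        ],
    )
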