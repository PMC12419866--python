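"""Workload outcomes derived from EHR audit-log event streams.

Two daily outcomes are computed from the click-level audit trail:

* **EHR time** — the sum of gaps between successive actions, dropping gaps
  longer than an inactivity threshold (default 5 minutes); a standard
  audit-log proxy for time actively spent on the EHR.
* **Patient switches** — the number of transitions between different
  patients' charts where the two chart events are within the inactivity
  threshold of each other; a proxy for attention switching.

Plus **patient load**, the number of distinct patients touched in the day.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

AUDIT_COLUMNS = ["clinician_id", "timestamp", "action_type", "patient_id", "login_context"]
ACTION_TYPES = frozenset({"note_sign", "order", "login", "chart_access", "other"})

DEFAULT_INACTIVITY_MIN = 5.0


def parse_audit_events(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a raw audit-log table.

    Empty strings in ``patient_id`` / ``login_context`` encode missingness
    and are converted to NA.
    """
    missing = [c for c in AUDIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"audit table missing columns: {missing}")
    out = df.copy()
    ts = pd.to_datetime(out["timestamp"], errors="coerce")
    if ts.isna().any():
        raise ValueError(f"unparseable timestamp at row index {ts.isna().idxmax()}")
    out["timestamp"] = ts
    bad = ~out["action_type"].isin(ACTION_TYPES)
    if bad.any():
        raise ValueError(f"unknown action_type at row index {bad.idxmax()}")
    for col in ("patient_id", "login_context"):
        out[col] = out[col].replace("", np.nan)
    return out


def _day_slice(events: pd.DataFrame, date) -> pd.DataFrame:
    if events.empty:
        return events
    date = pd.Timestamp(date).normalize()
    ts = events["timestamp"]
    day = events[(ts >= date) & (ts < date + pd.Timedelta(days=1))]
    # stable sort: ties keep input order
    return day.sort_values("timestamp", kind="stable")


def ehr_time(
    events: pd.DataFrame, date, inactivity_threshold: float = DEFAULT_INACTIVITY_MIN
) -> float:
    """Active EHR time in minutes for one clinician-day.

    Sums gaps between successive actions that are <= ``inactivity_threshold``
    minutes (inclusive at the threshold); longer gaps count as inactivity.
    Fewer than two events give 0.  Negative gaps (out-of-order duplicates)
    are treated as 0.
    """
    day = _day_slice(events, date)
    if len(day) < 2:
        return 0.0
    gaps = day["timestamp"].diff().dt.total_seconds().to_numpy()[1:]
    gaps = np.clip(gaps, 0.0, None)
    keep = gaps <= inactivity_threshold * 60.0
    return float(gaps[keep].sum() / 60.0)


def patient_switches(
    events: pd.DataFrame, date, inactivity_threshold: float = DEFAULT_INACTIVITY_MIN
) -> int:
    """Count of patient-chart switches for one clinician-day.

    Pairs are formed between consecutive *patient-attached* events
    (events without a patient id are skipped and do not reset the clock);
    a pair counts when the patient ids differ and the time between the two
    events is <= the threshold.
    """
    day = _day_slice(events, date)
    day = day[day["patient_id"].notna()]
    if len(day) < 2:
        return 0
    gaps = day["timestamp"].diff().dt.total_seconds().to_numpy()[1:]
    gaps = np.clip(gaps, 0.0, None)
    pids = day["patient_id"].to_numpy()
    differs = pids[1:] != pids[:-1]
    return int((differs & (gaps <= inactivity_threshold * 60.0)).sum())


def patient_load(events: pd.DataFrame, date) -> int:
    """Number of distinct non-missing patient ids touched during the day."""
    day = _day_slice(events, date)
    return int(day["patient_id"].nunique())


def summarize_audit(
    audit: pd.DataFrame, inactivity_threshold: float = DEFAULT_INACTIVITY_MIN
) -> pd.DataFrame:
    """Per clinician-day outcome summaries for a full audit-log table."""
    audit = parse_audit_events(audit)
    rows = []
    dates = audit["timestamp"].dt.normalize()
    for (clin, date), grp in audit.groupby([audit["clinician_id"], dates], sort=True):
        rows.append(
            {
                "clinician_id": clin,
                "date": date,
                "ehr_time": ehr_time(grp, date, inactivity_threshold),
                "n_switches": patient_switches(grp, date, inactivity_threshold),
                "patient_load": patient_load(grp, date),
            }
        )
    return pd.DataFrame(
        rows, columns=["clinician_id", "date", "ehr_time", "n_switches", "patient_load"]
    )
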