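"""Clinician-day cohort assembly: inclusion rules and service assignment.

A candidate clinician-day is any calendar day with messaging or audit
activity.  A day is analyzable when the clinician signed at least one note,
placed at least one order, sent or read at least one secure message, was not
on a night shift (first EHR login before 5 AM or after 5 PM), and has
complete demographics.  The daily clinical service is proxied by the modal
login context.
"""

from __future__ import annotations

import datetime as dt
import logging

import pandas as pd

from . import ehr_metrics, messaging_metrics

logger = logging.getLogger(__name__)

ROSTER_COLUMNS = ["clinician_id", "role", "age", "sex"]
ROLES = ("attending", "APP", "trainee")

#: First failing rule wins; each excluded day gets exactly one reason.
EXCLUSION_ORDER = [
    "no_note",
    "no_order",
    "no_message",
    "no_login",
    "night_shift",
    "missing_demographics",
]

NIGHT_START = dt.time(5, 0)   # first login strictly before 5 AM -> night
NIGHT_END = dt.time(17, 0)    # first login strictly after 5 PM -> night

COHORT_COLUMNS = [
    "clinician_id",
    "date",
    "role",
    "age",
    "sex",
    "service",
    "included",
    "exclusion_reason",
    "exposure",
    "max_concurrent",
    "msg_volume",
    "total_msg_time",
    "pct_concurrent_time",
    "ehr_time",
    "n_switches",
    "patient_load",
]


def parse_roster(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ROSTER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"roster missing columns: {missing}")
    out = df.copy()
    if out["clinician_id"].duplicated().any():
        dup = out.loc[out["clinician_id"].duplicated(), "clinician_id"].iloc[0]
        raise ValueError(f"duplicate clinician_id in roster: {dup!r}")
    out["age"] = pd.to_numeric(out["age"], errors="coerce")
    out["sex"] = out["sex"].replace("", pd.NA)
    return out


def is_night_shift(first_login: pd.Timestamp) -> bool:
    """Night shift iff the first login is before 5 AM or after 5 PM.

    Both boundaries are exclusive: a first login at exactly 05:00 or 17:00
    counts as a day shift.
    """
    t = pd.Timestamp(first_login).time()
    return t < NIGHT_START or t > NIGHT_END


def assign_service(login_events: pd.DataFrame) -> str | None:
    """Modal login context of the day; ties broken by earliest occurrence.

    Returns ``None`` when the day has no login with a context (such days
    are excluded upstream).
    """
    logins = login_events[
        (login_events["action_type"] == "login") & login_events["login_context"].notna()
    ]
    if logins.empty:
        return None
    logins = logins.sort_values("timestamp", kind="stable")
    stats = logins.groupby("login_context", sort=False)["timestamp"].agg(["count", "min"])
    stats = stats.sort_values(["count", "min"], ascending=[False, True], kind="stable")
    return stats.index[0]


def inclusion_status(
    audit_events: pd.DataFrame,
    message_events: pd.DataFrame,
    roster_row: pd.Series | None,
) -> tuple[bool, str]:
    """Apply the inclusion rules to one clinician-day.

    Returns ``(included, reason)`` with the first failing rule (in the
    fixed precedence order) as the reason, or ``"none"`` when included.
    A clinician absent from the roster counts as missing demographics.
    """
    actions = audit_events["action_type"]
    if not (actions == "note_sign").any():
        return False, "no_note"
    if not (actions == "order").any():
        return False, "no_order"
    if message_events.empty:
        return False, "no_message"
    logins = audit_events[actions == "login"]
    if logins.empty:
        return False, "no_login"
    if is_night_shift(logins["timestamp"].min()):
        return False, "night_shift"
    if roster_row is None or pd.isna(roster_row["age"]) or pd.isna(roster_row["sex"]):
        return False, "missing_demographics"
    return True, "none"


def build_cohort(
    messages: pd.DataFrame,
    audit_log: pd.DataFrame,
    roster: pd.DataFrame,
    bin_width: int = 1,
    inactivity_threshold: float = ehr_metrics.DEFAULT_INACTIVITY_MIN,
) -> tuple[pd.DataFrame, dict]:
    """Assemble the clinician-day cohort from the three input tables.

    Returns ``(cohort, report)`` where ``cohort`` has one row per candidate
    clinician-day (any messaging or audit activity) with metrics, inclusion
    flag and exclusion reason, and ``report`` counts days per exclusion
    reason plus the included and candidate totals.
    """
    messages = messaging_metrics.parse_message_events(messages)
    audit_log = ehr_metrics.parse_audit_events(audit_log)
    roster = parse_roster(roster)
    roster_ix = roster.set_index("clinician_id")

    msg_days = {
        key: grp
        for key, grp in messages.groupby(
            [messages["clinician_id"], messages["timestamp"].dt.normalize()], sort=True
        )
    }
    audit_days = {
        key: grp
        for key, grp in audit_log.groupby(
            [audit_log["clinician_id"], audit_log["timestamp"].dt.normalize()], sort=True
        )
    }
    candidates = sorted(set(msg_days) | set(audit_days))

    empty_msg = messages.iloc[0:0]
    empty_audit = audit_log.iloc[0:0]
    rows = []
    for clin, date in candidates:
        msg = msg_days.get((clin, date), empty_msg)
        aud = audit_days.get((clin, date), empty_audit)
        if clin in roster_ix.index:
            roster_row = roster_ix.loc[clin]
        else:
            roster_row = None
            logger.warning("clinician %s absent from roster; day %s excluded", clin, date)
        included, reason = inclusion_status(aud, msg, roster_row)
        msum = messaging_metrics.messaging_summary(msg, date, bin_width)
        rows.append(
            {
                "clinician_id": clin,
                "date": date,
                "role": None if roster_row is None else roster_row["role"],
                "age": None if roster_row is None else roster_row["age"],
                "sex": None if roster_row is None else roster_row["sex"],
                "service": assign_service(aud),
                "included": included,
                "exclusion_reason": reason,
                "exposure": msum.category.value,
                "max_concurrent": msum.max_concurrent,
                "msg_volume": msum.msg_volume,
                "total_msg_time": msum.total_msg_time,
                "pct_concurrent_time": msum.pct_concurrent_time,
                "ehr_time": ehr_metrics.ehr_time(aud, date, inactivity_threshold),
                "n_switches": ehr_metrics.patient_switches(aud, date, inactivity_threshold),
                "patient_load": ehr_metrics.patient_load(aud, date),
            }
        )
    cohort = pd.DataFrame(rows, columns=COHORT_COLUMNS)

    report = {reason: 0 for reason in EXCLUSION_ORDER}
    if len(cohort):
        counts = cohort.loc[~cohort["included"], "exclusion_reason"].value_counts()
        report.update({k: int(v) for k, v in counts.items()})
    report["included"] = int(cohort["included"].sum()) if len(cohort) else 0
    report["total_candidate_days"] = len(cohort)
    logger.info("cohort: %s", report)
    return cohort, report
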