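"""Synthetic secure-messaging metadata, audit logs, and clinician roster.

The generator produces the three input tables of the analysis pipeline with
known ground truth, so that every downstream stage — interval construction,
concurrency binning, EHR-time sessionization, switch counting, cohort rules,
and the mixed model — can be tested end to end, and so that planted
regression coefficients can be recovered.

Effects are planted on the *derived-metric* scale: for each clinician-day
the generator first realizes the messaging side (conversation threads whose
overlap structure determines the exposure category), then draws target
outcomes from the planted linear model

    y = intercept + beta[exposure] + beta_vol * msg_volume
        + beta_load * patient_load + b_clinician + b_service + eps,

and finally constructs an audit-log event stream whose *derived* EHR time
and patient-switch count reproduce those targets exactly (gaps are sized
below the inactivity threshold to hit the time budget; patient ids are
sequenced to realize the switch count; extra patients beyond the switch
budget are attached to events isolated by gaps above the threshold, which
add neither time nor switches).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .messaging_metrics import ExposureCategory, messaging_summary

logger = logging.getLogger(__name__)

ROLES = ("attending", "APP", "trainee")
OUTCOMES = ("ehr_time", "n_switches")
EXPOSURE_LEVELS = ("NONE", "TWO", "THREE", "FOUR_PLUS")

#: seconds; chain gaps are kept at or below this so every gap counts as
#: active time under the default 5-minute inactivity threshold.
_MAX_ACTIVE_GAP = 240
#: seconds; gaps strictly above the 5-minute threshold (never active time).
_IDLE_GAP = 310

FAIL_MODES = ("no_note", "no_order", "no_message", "no_login", "night_shift")


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults are calibrated to the descriptive scale of a large inpatient
    secure-messaging cohort: ~37 messages per clinician-day (median),
    roughly half of days with some conversational overlap, median daily
    patient load around 7, EHR time of a few hundred minutes, and planted
    exposure effects of 20.3/38.0/54.8 minutes (EHR time) and
    14.5/26.7/41.6 switches for 2/3/>=4 concurrent conversations versus
    none.
    """

    n_clinicians: int = 60
    n_days: int = 6
    role_mix: dict = field(
        default_factory=lambda: {"attending": 0.54, "APP": 0.27, "trainee": 0.19}
    )
    conversation_rate: float = 8.0  # mean threads per clinician-day
    overlap_intensity: float = 0.5  # P(new thread starts inside an open one)
    true_betas: dict = field(
        default_factory=lambda: {
            "ehr_time": {"TWO": 20.3, "THREE": 38.0, "FOUR_PLUS": 54.8},
            "n_switches": {"TWO": 14.5, "THREE": 26.7, "FOUR_PLUS": 41.6},
        }
    )
    intercepts: dict = field(
        default_factory=lambda: {"ehr_time": 200.0, "n_switches": 60.0}
    )
    covariate_betas: dict = field(
        default_factory=lambda: {
            "ehr_time": {"msg_volume": 0.37, "patient_load": 7.0},
            "n_switches": {"msg_volume": 0.28, "patient_load": 4.0},
        }
    )
    #: multiplies the exposure betas per role (all 1 => no interaction).
    role_scale: dict = field(
        default_factory=lambda: {"attending": 1.0, "APP": 1.0, "trainee": 1.0}
    )
    sigma_resid: dict = field(
        default_factory=lambda: {"ehr_time": 60.0, "n_switches": 40.0}
    )
    sigma_clinician: float = 30.0
    sigma_service: float = 15.0
    n_services: int = 8
    mean_patient_load: float = 6.0
    p_missing_demographics: float = 0.02
    night_shift_fraction: float = 0.10
    allow_midnight_spanning: bool = False
    start_date: str = "2023-02-01"
    seed: int = 0

    def validate(self) -> None:
        if self.n_clinicians < 1 or self.n_days < 1 or self.n_services < 1:
            raise ValueError("counts must be positive")
        if set(self.role_mix) != set(ROLES):
            raise ValueError(f"role_mix must have keys {ROLES}")
        if abs(sum(self.role_mix.values()) - 1.0) > 1e-9:
            raise ValueError("role_mix must sum to 1")
        if any(v < 0 for v in self.role_mix.values()):
            raise ValueError("role_mix proportions must be >= 0")
        for frac in (self.p_missing_demographics, self.night_shift_fraction,
                     self.overlap_intensity):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.conversation_rate < 0:
            raise ValueError("conversation_rate must be >= 0")
        if self.sigma_clinician < 0 or self.sigma_service < 0:
            raise ValueError("random-intercept SDs must be >= 0")
        if any(s < 0 for s in self.sigma_resid.values()):
            raise ValueError("residual SDs must be >= 0")


@dataclass
class DayPlan:
    """Realized exposure side and planted outcome targets for one day."""

    category: str
    msg_volume: int
    patient_load: int
    target_ehr_time: float  # minutes
    target_switches: int
    night_shift: bool = False
    service_context: str = "svc00"
    minority_context: str | None = None
    fail: str | None = None  # one of FAIL_MODES, or None


@dataclass
class SimResult:
    """The three generated tables plus the per-day ground truth."""

    messages: pd.DataFrame
    audit_log: pd.DataFrame
    roster: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig


def linear_predictor(
    config: SimConfig, outcome: str, category: str, msg_volume: float,
    patient_load: float, role: str,
) -> float:
    """Fixed-effect part of the planted outcome model (no noise)."""
    beta = config.true_betas[outcome].get(category, 0.0) * config.role_scale[role]
    cov = config.covariate_betas[outcome]
    return (
        config.intercepts[outcome]
        + beta
        + cov["msg_volume"] * msg_volume
        + cov["patient_load"] * patient_load
    )


def generate_roster(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Clinician roster with roles drawn from ``role_mix``.

    A ``p_missing_demographics`` fraction of clinicians has both age and
    sex absent (encoded as NA, never imputed).
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_clinicians
    roles = rng.choice(ROLES, size=n, p=[config.role_mix[r] for r in ROLES])
    # age by role: trainees younger, mirroring the usual demographic split
    age_mu = {"attending": 42.0, "APP": 40.0, "trainee": 30.0}
    ages = np.array([rng.normal(age_mu[r], 6.0) for r in roles]).round().clip(25, 75)
    sexes = rng.choice(["female", "male"], size=n, p=[0.56, 0.44])
    missing = rng.random(n) < config.p_missing_demographics
    roster = pd.DataFrame(
        {
            "clinician_id": [f"clin{i:04d}" for i in range(n)],
            "role": roles,
            "age": ages,
            "sex": sexes,
        }
    )
    roster.loc[missing, ["age", "sex"]] = np.nan
    return roster


def generate_messaging_day(
    clinician_id: str, date, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Message activities for one clinician-day, grouped into threads.

    Thread count is Poisson(``conversation_rate``).  With probability
    ``overlap_intensity`` a new thread starts inside an already-open one
    (forcing overlap); otherwise it starts after every open thread has
    ended, so ``overlap_intensity=0`` yields pairwise-disjoint threads.
    Thread durations are log-normal (median ~40 min).  Each thread carries
    its first and last activity plus a Poisson number of interior ones.
    """
    date = pd.Timestamp(date).normalize()
    n_conv = rng.poisson(config.conversation_rate) if config.conversation_rate > 0 else 0
    rows: list[tuple] = []
    intervals: list[tuple[int, int]] = []
    day_end = 86400 if config.allow_midnight_spanning else 86399
    for i in range(n_conv):
        duration = int(np.clip(rng.lognormal(math.log(40 * 60), 1.0), 60, 6 * 3600))
        if intervals and rng.random() < config.overlap_intensity:
            s0, e0 = intervals[rng.integers(len(intervals))]
            start = int(rng.integers(s0, max(s0 + 1, min(e0, 86340))))
        else:
            # distinct conversation episodes sit several minutes apart;
            # the 5-minute floor keeps disjoint threads in different bins
            # at every supported bin width
            last_end = max((e for _, e in intervals), default=7 * 3600)
            start = last_end + 300 + int(rng.exponential(1200.0))
        if start >= 86100:  # too close to midnight to host a thread
            continue
        end = start + duration
        if not config.allow_midnight_spanning:
            end = min(end, day_end)
        intervals.append((start, end))
        n_inner = rng.poisson(2.5)
        times = {start, end} | {
            int(t) for t in rng.integers(start, max(start + 1, end), size=n_inner)
        }
        conv_id = f"c-{clinician_id}-{date.date()}-{i:03d}"
        for t in sorted(times):
            direction = "sent" if rng.random() < 0.45 else "read"
            rows.append((conv_id, clinician_id, direction, date + pd.Timedelta(seconds=t)))
    return pd.DataFrame(rows, columns=["conversation_id", "clinician_id", "direction", "timestamp"])


def _chain_gaps(total_seconds: int, n_gaps: int) -> np.ndarray:
    """Split ``total_seconds`` into ``n_gaps`` integers, each <= 5 minutes."""
    base, rem = divmod(total_seconds, n_gaps)
    return np.array([base + 1] * rem + [base] * (n_gaps - rem), dtype=int)


def generate_audit_day(
    clinician_id: str, date, plan: DayPlan, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Audit-log events for one clinician-day hitting the planted targets.

    The derived EHR time equals ``plan.target_ehr_time`` (to the second)
    and the derived switch count equals ``plan.target_switches``, unless
    the day-shift window cannot hold the time budget, in which case the
    budget is clipped with a warning.  The stream includes a login (with
    the day's service context), at least one signed note and one order
    (unless the plan requests a specific inclusion-rule failure), and a
    patient-less ``other`` event to exercise the switch rule's skipping.
    """
    date = pd.Timestamp(date).normalize()
    fail = plan.fail
    if fail is not None and fail not in FAIL_MODES:
        raise ValueError(f"unknown fail mode {fail!r}")
    night = plan.night_shift or fail == "night_shift"

    if night:
        # evening or pre-dawn start; either satisfies the night-shift rule
        start_sec = int(rng.choice([2 * 3600, 19 * 3600]) + rng.integers(0, 1800))
    else:
        start_sec = int(6 * 3600 + rng.integers(1800, 7200))  # 06:30-08:00

    rows: list[tuple] = []  # (timestamp_sec, action_type, patient_id, login_context)
    if fail != "no_login":
        rows.append((start_sec, "login", None, plan.service_context))

    chain_start = start_sec + 400  # idle gap: the login adds no active time
    target_minutes = plan.target_ehr_time
    if target_minutes > 1440:
        logger.warning(
            "clinician %s %s: requested EHR time %.1f min exceeds a day; clipped",
            clinician_id, date.date(), target_minutes,
        )
    total = int(round(max(0.0, min(target_minutes, 1440.0)) * 60))
    # reserve room for isolated extra-patient events before midnight
    available = 86399 - chain_start - (plan.patient_load + 2) * _IDLE_GAP
    if total > available:
        logger.warning(
            "clinician %s %s: EHR-time budget %.1f min clipped to the day window",
            clinician_id, date.date(), total / 60.0,
        )
        total = max(0, available)

    load = max(0, int(plan.patient_load))
    switches = max(0, int(plan.target_switches))
    if load <= 1:
        switches = 0
    n_cycle = min(load, switches + 1) if load else 0
    patients = [f"pat-{clinician_id}-{i:03d}" for i in range(load)]

    n_gaps = max(math.ceil(total / _MAX_ACTIVE_GAP) if total else 0, switches, 2)
    gaps = _chain_gaps(total, n_gaps)
    times = chain_start + np.concatenate([[0], np.cumsum(gaps)])

    actions = ["chart_access"] * len(times)
    if fail != "no_note":
        actions[0] = "note_sign"
    if fail != "no_order":
        actions[1] = "order"
    for j, t in enumerate(times):
        if patients:
            pid = patients[min(j, switches) % n_cycle]
        else:
            pid = None
        rows.append((int(t), actions[j], pid, None))

    # a patient-less interloper mid-chain: splits one active gap in two,
    # changing neither the time sum nor the patient-attached adjacency
    mid = len(times) // 2
    if mid >= 1:
        rows.append((int(times[mid]), "other", None, None))

    # occasional second login(s): dominant context stays modal, the
    # minority context exercises the most-frequent-context tie handling
    if plan.minority_context is not None and len(times) >= 4 and fail != "no_login":
        rows.append((int(times[len(times) // 3]), "login", None, plan.service_context))
        rows.append((int(times[2 * len(times) // 3]), "login", None, plan.minority_context))

    # patients beyond the switch budget: isolated events separated by
    # above-threshold gaps (no time, no switches)
    t_extra = int(times[-1])
    for i in range(n_cycle, load):
        t_extra += _IDLE_GAP
        if t_extra > 86399:
            logger.warning("clinician %s %s: day too full for %d extra patients",
                           clinician_id, date.date(), load - i)
            break
        rows.append((t_extra, "chart_access", patients[i], None))

    rows.sort(key=lambda r: r[0])
    out = pd.DataFrame(rows, columns=["_sec", "action_type", "patient_id", "login_context"])
    out.insert(0, "clinician_id", clinician_id)
    out.insert(1, "timestamp", date + pd.to_timedelta(out.pop("_sec"), unit="s"))
    return out


def generate_day(
    clinician_id: str,
    date,
    config: SimConfig,
    rng: np.random.Generator,
    role: str = "attending",
    fail: str | None = None,
    b_clinician: float = 0.0,
    b_service: float = 0.0,
    service_context: str = "svc00",
) -> tuple[pd.DataFrame, pd.DataFrame, DayPlan]:
    """One clinician-day: messaging, audit log, and the realized plan.

    ``fail`` forces the day to violate exactly one inclusion rule, for use
    as a filter fixture.
    """
    date = pd.Timestamp(date).normalize()
    if fail == "no_message":
        messages = generate_messaging_day(clinician_id, date, replace(config), rng).iloc[0:0]
    else:
        messages = generate_messaging_day(clinician_id, date, config, rng)
    msum = messaging_summary(messages, date)
    patient_load = 1 + int(rng.poisson(config.mean_patient_load))
    targets = {}
    for outcome in OUTCOMES:
        lp = linear_predictor(
            config, outcome, msum.category.value, msum.msg_volume, patient_load, role
        )
        eps = rng.normal(0.0, config.sigma_resid[outcome])
        targets[outcome] = lp + b_clinician + b_service + eps
    plan = DayPlan(
        category=msum.category.value,
        msg_volume=msum.msg_volume,
        patient_load=patient_load,
        target_ehr_time=float(np.clip(targets["ehr_time"], 0.0, 1440.0)),
        target_switches=max(0, int(round(targets["n_switches"]))),
        night_shift=bool(rng.random() < config.night_shift_fraction),
        service_context=service_context,
        minority_context=None,
        fail=fail,
    )
    audit = generate_audit_day(clinician_id, date, plan, config, rng)
    return messages, audit, plan


def simulate_dataset(config: SimConfig) -> SimResult:
    """Full deterministic simulation of the three tables plus ground truth.

    Clinician and service random intercepts are drawn once and shared
    across that clinician's (service's) days, matching the crossed
    random-intercept structure of the planted model.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    roster = generate_roster(config, rng)
    services = [f"svc{i:02d}" for i in range(config.n_services)]
    b_clin = rng.normal(0.0, config.sigma_clinician, config.n_clinicians)
    b_svc = rng.normal(0.0, config.sigma_service, config.n_services)
    home_svc = rng.integers(0, config.n_services, config.n_clinicians)
    start = pd.Timestamp(config.start_date)

    msg_parts, audit_parts, truth_rows = [], [], []
    for i, clin in enumerate(roster.itertuples(index=False)):
        role = clin.role
        svc_idx = int(home_svc[i])
        for d in range(config.n_days):
            date = start + pd.Timedelta(days=d)
            messages = generate_messaging_day(clin.clinician_id, date, config, rng)
            msum = messaging_summary(messages, date)
            patient_load = 1 + int(rng.poisson(config.mean_patient_load))
            targets = {}
            for outcome in OUTCOMES:
                lp = linear_predictor(
                    config, outcome, msum.category.value, msum.msg_volume,
                    patient_load, role,
                )
                targets[outcome] = (
                    lp + b_clin[i] + b_svc[svc_idx]
                    + rng.normal(0.0, config.sigma_resid[outcome])
                )
            minority = None
            if config.n_services > 1 and rng.random() < 0.25:
                minority = services[(svc_idx + 1 + int(rng.integers(config.n_services - 1)))
                                    % config.n_services]
            plan = DayPlan(
                category=msum.category.value,
                msg_volume=msum.msg_volume,
                patient_load=patient_load,
                target_ehr_time=float(np.clip(targets["ehr_time"], 0.0, 1440.0)),
                target_switches=max(0, int(round(targets["n_switches"]))),
                night_shift=bool(rng.random() < config.night_shift_fraction),
                service_context=services[svc_idx],
                minority_context=minority,
            )
            audit = generate_audit_day(clin.clinician_id, date, plan, config, rng)
            msg_parts.append(messages)
            audit_parts.append(audit)
            demographics_ok = not (pd.isna(clin.age) or pd.isna(clin.sex))
            truth_rows.append(
                {
                    "clinician_id": clin.clinician_id,
                    "date": date,
                    "role": role,
                    "service": services[svc_idx],
                    "exposure": plan.category,
                    "msg_volume": plan.msg_volume,
                    "patient_load": plan.patient_load,
                    "target_ehr_time": plan.target_ehr_time,
                    "target_switches": plan.target_switches,
                    "night_shift": plan.night_shift,
                    "b_clinician": b_clin[i],
                    "b_service": b_svc[svc_idx],
                    "intended_included": demographics_ok and not plan.night_shift,
                }
            )
    messages = pd.concat(msg_parts, ignore_index=True) if msg_parts else pd.DataFrame(
        columns=["conversation_id", "clinician_id", "direction", "timestamp"]
    )
    audit_log = pd.concat(audit_parts, ignore_index=True) if audit_parts else pd.DataFrame(
        columns=["clinician_id", "timestamp", "action_type", "patient_id", "login_context"]
    )
    return SimResult(
        messages=messages,
        audit_log=audit_log,
        roster=roster,
        truth=pd.DataFrame(truth_rows),
        config=config,
    )


def simulate_cohort_table(
    config: SimConfig, rng: np.random.Generator | None = None, n_days: int | None = None
) -> pd.DataFrame:
    """Draw the analyzable clinician-day table directly from the planted model.

    Skips event-level construction (whose fidelity is checked separately by
    the round-trip tests) and samples exposure categories, covariates, and
    outcomes on the derived-metric scale.  Used for Monte-Carlo recovery
    and coverage studies where hundreds of replicates are needed.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_days = n_days if n_days is not None else config.n_days
    roster = generate_roster(config, rng)
    roster = roster.fillna({"age": 40.0, "sex": "female"})  # analyzable table only
    n = config.n_clinicians * n_days
    clin_idx = np.repeat(np.arange(config.n_clinicians), n_days)
    svc_of_day = rng.integers(0, config.n_services, n)
    b_clin = rng.normal(0.0, config.sigma_clinician, config.n_clinicians)
    b_svc = rng.normal(0.0, config.sigma_service, config.n_services)

    category = rng.choice(EXPOSURE_LEVELS, size=n, p=[0.45, 0.25, 0.15, 0.15])
    # busier messaging days tend to have more overlap: volume scales with category
    vol_scale = np.select(
        [category == lvl for lvl in EXPOSURE_LEVELS], [0.8, 1.1, 1.4, 1.8]
    )
    msg_volume = np.clip(
        rng.lognormal(math.log(37.0), 0.9, n) * vol_scale, 1, 600
    ).round()
    patient_load = 1 + rng.poisson(config.mean_patient_load, n)
    pct_concurrent = np.where(category == "NONE", 0.0, rng.uniform(5.0, 80.0, n))

    roles = roster["role"].to_numpy()[clin_idx]
    rows = {}
    for outcome in OUTCOMES:
        beta = np.array(
            [config.true_betas[outcome].get(c, 0.0) for c in category]
        ) * np.array([config.role_scale[r] for r in roles])
        cov = config.covariate_betas[outcome]
        lp = (
            config.intercepts[outcome]
            + beta
            + cov["msg_volume"] * msg_volume
            + cov["patient_load"] * patient_load
            + b_clin[clin_idx]
            + b_svc[svc_of_day]
        )
        y = lp + rng.normal(0.0, config.sigma_resid[outcome], n)
        rows[outcome] = y
    start = pd.Timestamp(config.start_date)
    out = pd.DataFrame(
        {
            "clinician_id": roster["clinician_id"].to_numpy()[clin_idx],
            "date": start + pd.to_timedelta(np.tile(np.arange(n_days), config.n_clinicians), unit="D"),
            "role": roles,
            "age": roster["age"].to_numpy()[clin_idx],
            "sex": roster["sex"].to_numpy()[clin_idx],
            "service": np.array([f"svc{i:02d}" for i in range(config.n_services)])[svc_of_day],
            "included": True,
            "exclusion_reason": "none",
            "exposure": category,
            "max_concurrent": np.select(
                [category == lvl for lvl in EXPOSURE_LEVELS], [1, 2, 3, 4]
            ),
            "msg_volume": msg_volume,
            "total_msg_time": np.clip(msg_volume * 5.0, 0, 1440),
            "pct_concurrent_time": pct_concurrent,
            "ehr_time": np.clip(rows["ehr_time"], 0.0, 1440.0),
            "n_switches": np.maximum(0, np.round(rows["n_switches"])).astype(int),
            "patient_load": patient_load,
        }
    )
    return out


def write_dataset(result: SimResult, outdir) -> dict:
    """Write the three tables (and ground truth) as CSV; returns the paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in [
        ("messages", result.messages),
        ("audit_log", result.audit_log),
        ("roster", result.roster),
        ("truth", result.truth),
    ]:
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths
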