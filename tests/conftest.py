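import numpy as np
import pandas as pd
import pytest

from convoload import SimConfig, simulate_dataset


def make_message_events(spec, clinician_id="clin-a", date="2023-02-01"):
    """Build a message-event frame from (conversation_id, 'HH:MM') pairs."""
    date = pd.Timestamp(date)
    rows = []
    for conv, hhmm in spec:
        rows.append(
            {
                "conversation_id": conv,
                "clinician_id": clinician_id,
                "direction": "sent",
                "timestamp": pd.Timestamp(f"{date.date()} {hhmm}"),
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture
def fig1_events():
    """Three conversation threads active 8:30-11:00, 8:40-10:30, 9:30-11:30."""
    return make_message_events(
        [
            ("c1", "08:30"), ("c1", "09:45"), ("c1", "11:00"),
            ("c2", "08:40"), ("c2", "10:30"),
            ("c3", "09:30"), ("c3", "11:30"),
        ]
    )


@pytest.fixture(scope="session")
def small_sim():
    """One modest event-level simulation shared across tests."""
    return simulate_dataset(SimConfig(n_clinicians=20, n_days=4, seed=7))


def random_intervals(rng, n, date="2023-02-01", p_zero_length=0.2):
    """Random within-day intervals (seconds resolution), some zero-length."""
    date = pd.Timestamp(date)
    start = rng.integers(0, 86000, n)
    length = np.where(
        rng.random(n) < p_zero_length, 0, rng.integers(1, 4 * 3600, n)
    )
    end = np.minimum(start + length, 86399)
    return pd.DataFrame(
        {
            "conversation_id": [f"c{i}" for i in range(n)],
            "clinician_id": "clin-a",
            "date": date,
            "start": date + pd.to_timedelta(start, unit="s"),
            "end": date + pd.to_timedelta(end, unit="s"),
        }
    )


def random_audit_events(rng, n, date="2023-02-01", p_patientless=0.3, max_gap=600):
    """Random audit stream with duplicate timestamps and patient-less rows."""
    date = pd.Timestamp(date)
    gaps = rng.integers(0, max_gap, n - 1)
    secs = 3600 + np.concatenate([[0], np.cumsum(gaps)])
    secs = np.minimum(secs, 86399)
    pids = np.array([f"p{j}" for j in rng.integers(0, 6, n)], dtype=object)
    pids[rng.random(n) < p_patientless] = None
    return pd.DataFrame(
        {
            "clinician_id": "clin-a",
            "timestamp": date + pd.to_timedelta(secs, unit="s"),
            "action_type": "chart_access",
            "patient_id": pids,
            "login_context": None,
        }
    )
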