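"""Descriptive statistics and pipeline orchestration.

``describe_cohort`` produces the descriptive table (medians with IQRs,
frequencies with percentages) per clinician role and overall;
``run_pipeline`` chains simulate -> build -> fit -> report with provenance
(the configuration and per-stage row counts are written into the run
directory).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import models, synthetic_data
from .models import ModelSpec

logger = logging.getLogger(__name__)

_MEDIAN_METRICS = [
    "ehr_time",
    "n_switches",
    "patient_load",
    "msg_volume",
    "total_msg_time",
    "pct_concurrent_time",
    "age",
]
_EXPOSURE_LEVELS = ("NONE", "TWO", "THREE", "FOUR_PLUS")


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    output_dir: str = "run"
    messages_path: str | None = None
    audit_log_path: str | None = None
    roster_path: str | None = None
    simulate: bool = True
    sim: synthetic_data.SimConfig = field(default_factory=synthetic_data.SimConfig)
    bin_width: int = 1
    inactivity_threshold: float = 5.0
    outcomes: tuple = ("ehr_time", "n_switches")
    stratify: bool = False
    backend: str = "vc"
    seed: int | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        cfg = cls(**raw)
        cfg.sim = synthetic_data.SimConfig(**sim_raw)
        if cfg.seed is not None:
            cfg.sim.seed = cfg.seed
        return cfg

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["outcomes"] = list(self.outcomes)
        return out


def describe_cohort(cohort: pd.DataFrame, included_only: bool = True) -> pd.DataFrame:
    """Tidy descriptive table: per role and overall, median/IQR of the
    daily metrics, exposure-category frequencies with percentages, and
    demographic summaries.

    Returns columns ``group, metric, statistic, value``; percentages per
    exposure category sum to 100 within each group.
    """
    if cohort.empty:
        raise ValueError("cannot describe an empty cohort")
    df = cohort[cohort["included"]] if included_only and "included" in cohort.columns else cohort
    if df.empty:
        raise ValueError("no included clinician-days to describe")
    groups = {"overall": df}
    for role, sub in df.groupby("role"):
        groups[str(role)] = sub
    rows = []
    for name, sub in groups.items():
        rows.append((name, "clinician_days", "n", float(len(sub))))
        rows.append((name, "clinicians", "n", float(sub["clinician_id"].nunique())))
        for metric in _MEDIAN_METRICS:
            if metric not in sub.columns:
                continue
            vals = pd.to_numeric(sub[metric], errors="coerce").dropna()
            if vals.empty:
                continue
            rows.append((name, metric, "median", float(vals.median())))
            rows.append((name, metric, "q1", float(vals.quantile(0.25))))
            rows.append((name, metric, "q3", float(vals.quantile(0.75))))
        for lvl in _EXPOSURE_LEVELS:
            n_lvl = int((sub["exposure"] == lvl).sum())
            rows.append((name, f"exposure_{lvl}", "n", float(n_lvl)))
            rows.append((name, f"exposure_{lvl}", "pct", 100.0 * n_lvl / len(sub)))
        if "sex" in sub.columns:
            n_f = int((sub["sex"] == "female").sum())
            rows.append((name, "sex_female", "n", float(n_f)))
            rows.append((name, "sex_female", "pct", 100.0 * n_f / len(sub)))
    return pd.DataFrame(rows, columns=["group", "metric", "statistic", "value"])


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline and return the run directory.

    Stages: (optional) simulate the three input tables; build the cohort;
    fit the mixed models (pooled, and stratified by role when requested);
    write the descriptive report.  Every stage logs row counts; outputs and
    the verbatim configuration land in ``config.output_dir``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "run_config.yaml").write_text(yaml.safe_dump(config.to_dict()))

    if config.simulate:
        result = synthetic_data.simulate_dataset(config.sim)
        paths = synthetic_data.write_dataset(result, outdir / "inputs")
        messages_path = paths["messages"]
        audit_path = paths["audit_log"]
        roster_path = paths["roster"]
    else:
        for name, p in [
            ("messages", config.messages_path),
            ("audit_log", config.audit_log_path),
            ("roster", config.roster_path),
        ]:
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"missing input file for {name}: {p}")
        messages_path = Path(config.messages_path)
        audit_path = Path(config.audit_log_path)
        roster_path = Path(config.roster_path)

    provenance = {
        "config_hash": hashlib.sha256(
            yaml.safe_dump(config.to_dict()).encode()
        ).hexdigest()[:16],
        "input_hashes": {
            "messages": _hash_file(Path(messages_path)),
            "audit_log": _hash_file(Path(audit_path)),
            "roster": _hash_file(Path(roster_path)),
        },
    }

    messages = pd.read_csv(messages_path)
    audit_log = pd.read_csv(audit_path)
    roster = pd.read_csv(roster_path)
    logger.info(
        "inputs: %d messages, %d audit events, %d clinicians",
        len(messages), len(audit_log), len(roster),
    )

    cohort, report = cohort_mod.build_cohort(
        messages, audit_log, roster,
        bin_width=config.bin_width,
        inactivity_threshold=config.inactivity_threshold,
    )
    cohort.to_csv(outdir / "cohort.csv", index=False)
    (outdir / "exclusion_report.json").write_text(json.dumps(report, indent=2))
    logger.info("cohort: %d candidate days, %d included", len(cohort), report["included"])

    metadata = {"provenance": provenance, "models": {}}
    for outcome in config.outcomes:
        table = models.fit_lmm(cohort, ModelSpec(outcome=outcome), backend=config.backend)
        table.to_frame().to_csv(outdir / f"effects_{outcome}.csv", index=False)
        metadata["models"][outcome] = {
            "var_clinician": table.var_clinician,
            "var_service": table.var_service,
            "var_resid": table.var_resid,
            "n_obs": table.n_obs,
            "n_clinicians": table.n_clinicians,
            "n_services": table.n_services,
            "method": table.method,
            "backend": table.backend,
            "converged": table.converged,
        }
        if config.stratify:
            for role, tab in models.stratified_fits(
                cohort, ModelSpec(outcome=outcome), backend=config.backend
            ).items():
                tab.to_frame().to_csv(
                    outdir / f"effects_{outcome}_{role}.csv", index=False
                )
    (outdir / "model_metadata.json").write_text(json.dumps(metadata, indent=2))

    describe_cohort(cohort).to_csv(outdir / "descriptive_table.csv", index=False)
    logger.info("run complete: %s", outdir)
    return outdir
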