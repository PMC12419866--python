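"""Mixed-model estimation: recovery, degeneracies, and reference backends."""

import json
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from convoload import SimConfig, simulate_cohort_table
from convoload.models import (
    EffectTable,
    ModelSpec,
    fit_lmm,
    interaction_test,
    stratified_fits,
)

EXPOSURE_TERMS = ("exposure[TWO]", "exposure[THREE]", "exposure[FOUR_PLUS]")
TRUE_EHR = {"exposure[TWO]": 20.3, "exposure[THREE]": 38.0, "exposure[FOUR_PLUS]": 54.8}


@pytest.fixture(scope="module")
def medium_cohort():
    return simulate_cohort_table(SimConfig(n_clinicians=120, n_days=15, seed=31))


class TestFitLmm:
    def test_noiseless_cohort_returns_planted_betas(self):
        cfg = SimConfig(
            n_clinicians=80, n_days=10, seed=5,
            sigma_resid={"ehr_time": 0.0, "n_switches": 0.0},
            sigma_clinician=0.0, sigma_service=0.0,
        )
        tab = simulate_cohort_table(cfg)
        table = fit_lmm(tab, ModelSpec(outcome="ehr_time"))
        for term, true in TRUE_EHR.items():
            assert table.estimate(term) == pytest.approx(true, abs=1e-4)
        assert table.estimate("msg_volume") == pytest.approx(0.37, abs=1e-5)
        assert table.estimate("patient_load") == pytest.approx(7.0, abs=1e-4)

    def test_stochastic_cohort_cis_cover_planted_betas(self, medium_cohort):
        table = fit_lmm(medium_cohort, ModelSpec(outcome="ehr_time"))
        assert table.converged
        for term, true in TRUE_EHR.items():
            lo, hi = table.ci(term)
            assert lo < true < hi
            assert lo < table.estimate(term) < hi

    def test_variance_components_near_generator_sds(self, medium_cohort):
        table = fit_lmm(medium_cohort, ModelSpec(outcome="ehr_time"))
        assert np.sqrt(table.var_resid) == pytest.approx(60.0, rel=0.15)
        assert np.sqrt(table.var_clinician) == pytest.approx(30.0, rel=0.5)

    def test_constant_outcome_flags_zero_residual_variance(self, medium_cohort):
        tab = medium_cohort.copy()
        tab["ehr_time"] = 250.0
        with pytest.warns(UserWarning, match="constant"):
            table = fit_lmm(tab, ModelSpec(outcome="ehr_time"))
        assert table.var_resid == 0.0
        slopes = table.terms[table.terms["term"] != "Intercept"]["estimate"]
        assert (slopes == 0.0).all()
        assert table.estimate("Intercept") == 250.0

    def test_missing_exposure_level_is_explicit_error(self, medium_cohort):
        tab = medium_cohort[medium_cohort["exposure"] != "THREE"]
        with pytest.raises(ValueError, match="exposure.*THREE"):
            fit_lmm(tab, ModelSpec(outcome="ehr_time"))

    def test_single_clinician_rejected(self, medium_cohort):
        one = medium_cohort[medium_cohort["clinician_id"] == "clin0000"]
        with pytest.raises(ValueError, match="clinicians"):
            fit_lmm(one, ModelSpec(outcome="ehr_time"))

    def test_adding_constant_shifts_only_intercept(self, medium_cohort):
        base = fit_lmm(medium_cohort, ModelSpec(outcome="ehr_time"))
        shifted_tab = medium_cohort.copy()
        shifted_tab["ehr_time"] = shifted_tab["ehr_time"] + 100.0
        shifted = fit_lmm(shifted_tab, ModelSpec(outcome="ehr_time"))
        assert shifted.estimate("Intercept") == pytest.approx(
            base.estimate("Intercept") + 100.0, abs=1e-3
        )
        for term in base.terms["term"][1:]:
            assert shifted.estimate(term) == pytest.approx(base.estimate(term), abs=1e-3)

    def test_zero_variance_generator_matches_ols(self):
        """With no random-intercept variance the LMM collapses to OLS."""
        cfg = SimConfig(
            n_clinicians=100, n_days=8, seed=9,
            sigma_clinician=0.0, sigma_service=0.0,
        )
        tab = simulate_cohort_table(cfg)
        lmm = fit_lmm(tab, ModelSpec(outcome="ehr_time"))
        from convoload.models import build_design, _prepare

        df = _prepare(tab, ModelSpec(outcome="ehr_time"))
        X, names, y = build_design(df, ModelSpec(outcome="ehr_time"))
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        # REML variance estimates are only ~0 at finite n, so agreement is
        # close but not exact
        np.testing.assert_allclose(lmm.terms["estimate"].to_numpy(), ols, atol=0.5)


@pytest.fixture(scope="module")
def fixture_cohort():
    return simulate_cohort_table(SimConfig(n_clinicians=40, n_days=15,
                                           n_services=6, seed=21))


class TestCrossChecks:
    def test_vc_backend_matches_statsmodels_mixedlm(self, fixture_cohort):
        vc = fit_lmm(fixture_cohort, ModelSpec(outcome="ehr_time"), backend="vc")
        sm = fit_lmm(fixture_cohort, ModelSpec(outcome="ehr_time"), backend="statsmodels")
        # same model, two optimizers: agreement to well below an SE
        np.testing.assert_allclose(
            vc.terms["estimate"].to_numpy(), sm.terms["estimate"].to_numpy(), atol=0.5
        )
        assert vc.var_resid == pytest.approx(sm.var_resid, rel=0.05)
        # the profiled fitter must never find a worse restricted likelihood
        assert vc.loglik >= sm.loglik - 1e-3

    def test_vc_backend_matches_lme4(self, fixture_cohort, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        data_path = tmp_path / "cohort.csv"
        fixture_cohort.to_csv(data_path, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4)); suppressMessages(library(jsonlite))
            d <- read.csv("{data_path}")
            d$exposure <- relevel(factor(d$exposure), ref="NONE")
            d$role <- relevel(factor(d$role), ref="attending")
            d$sex <- relevel(factor(d$sex), ref="female")
            m <- lmer(ehr_time ~ exposure + pct_concurrent_time + msg_volume +
                      patient_load + role + age + sex +
                      (1|clinician_id) + (1|service), data=d, REML=TRUE)
            vc <- as.data.frame(VarCorr(m))
            cat(toJSON(list(fixef=as.list(fixef(m)),
                            vcov=setNames(as.list(vc$vcov), vc$grp)), digits=10))
        """))
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        ref = json.loads(out.stdout)
        table = fit_lmm(fixture_cohort, ModelSpec(outcome="ehr_time"))
        name_map = {
            "(Intercept)": "Intercept",
            "exposureTWO": "exposure[TWO]",
            "exposureTHREE": "exposure[THREE]",
            "exposureFOUR_PLUS": "exposure[FOUR_PLUS]",
            "pct_concurrent_time": "pct_concurrent_time",
            "msg_volume": "msg_volume",
            "patient_load": "patient_load",
            "roleAPP": "role[APP]",
            "roletrainee": "role[trainee]",
            "age": "age",
            "sexmale": "sex[male]",
        }
        for r_name, our_name in name_map.items():
            assert table.estimate(our_name) == pytest.approx(
                ref["fixef"][r_name][0], abs=2e-3
            ), our_name
        assert table.var_clinician == pytest.approx(ref["vcov"]["clinician_id"][0], rel=0.01)
        assert table.var_service == pytest.approx(ref["vcov"]["service"][0], rel=0.01)
        assert table.var_resid == pytest.approx(ref["vcov"]["Residual"][0], rel=0.01)


class TestInteractionAndStrata:
    def test_null_interaction_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(77)
        pvals = []
        for rep in range(25):
            cfg = SimConfig(n_clinicians=80, n_days=12, seed=0)
            tab = simulate_cohort_table(cfg, rng=rng)
            p, _ = interaction_test(tab, ModelSpec(outcome="ehr_time"))
            pvals.append(p)
        rejections = sum(p < 0.2 for p in pvals)
        # Binomial(25, .2): central 99.9% range
        assert 0 <= rejections <= 13

    def test_planted_role_difference_detected(self):
        cfg = SimConfig(
            n_clinicians=200, n_days=25, seed=55,
            role_scale={"attending": 1.0, "APP": 1.0, "trainee": 1.5},
        )
        tab = simulate_cohort_table(cfg)
        p, full = interaction_test(tab, ModelSpec(outcome="ehr_time"))
        assert p < 0.05
        assert "exposure[FOUR_PLUS]:role[trainee]" in set(full.terms["term"])

    def test_single_role_cohort_is_precondition_error(self, medium_cohort):
        one_role = medium_cohort[medium_cohort["role"] == "attending"]
        with pytest.raises(ValueError, match="roles"):
            interaction_test(one_role, ModelSpec(outcome="ehr_time"))

    def test_strata_recover_role_specific_betas(self):
        cfg = SimConfig(
            n_clinicians=150, n_days=20, seed=61,
            role_scale={"attending": 1.0, "APP": 0.6, "trainee": 1.5},
            sigma_resid={"ehr_time": 20.0, "n_switches": 15.0},
        )
        tab = simulate_cohort_table(cfg)
        fits = stratified_fits(tab, ModelSpec(outcome="ehr_time"))
        assert set(fits) == {"attending", "APP", "trainee"}
        for role, scale in cfg.role_scale.items():
            table = fits[role]
            assert "role[APP]" not in set(table.terms["term"])
            for term, true in TRUE_EHR.items():
                lo, hi = table.ci(term)
                se = (hi - lo) / (2 * 1.96)
                # within 3.3 SE of the stratum's own planted effect
                assert abs(table.estimate(term) - true * scale) < 3.3 * se, (role, term)

    def test_single_service_stratum_reports_zero_service_variance(self, medium_cohort):
        sub = medium_cohort[medium_cohort["service"] == "svc00"].copy()
        assert sub["exposure"].nunique() == 4
        with pytest.warns(UserWarning, match="single service"):
            table = fit_lmm(sub, ModelSpec(outcome="ehr_time"))
        assert table.var_service == 0.0
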