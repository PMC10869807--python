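import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from invaphylo.glmm import DesignError, add_intercept, fit_mixed_model
from invaphylo.inference import (
    ModelSpec,
    SEMConfig,
    choose_link,
    fit_occurrence_glmm,
    fit_sem,
    r2_nakagawa,
    r2_nakagawa_components,
    vif,
)
from invaphylo.synthetic_data import simulate_glmm_records, simulate_sem_records


@pytest.fixture(scope="module")
def glmm_records():
    return simulate_glmm_records(seed=42, n_species=60, n_countries=4,
                                 basins_per_country=8)


class TestModelSpec:
    def test_requires_exactly_one_relatedness_predictor(self):
        with pytest.raises(ValueError):
            ModelSpec(predictors=["mpd_z", "mntd_z"])
        with pytest.raises(ValueError):
            ModelSpec(predictors=["native_richness_z"])

    def test_unknown_link_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(predictors=["mpd_z"], link="probit")


class TestFitOccurrenceGLMM:
    def test_zero_variance_fit_matches_plain_logistic_oracle(self):
        # no group structure in the data; SDs pinned at (near) zero
        rng = np.random.default_rng(10)
        n = 600
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-0.4 - 0.6 * x)))).astype(float)
        X = pd.DataFrame({"(Intercept)": 1.0, "mpd_z": x})
        fit = fit_mixed_model(
            y,
            X,
            {"species": rng.integers(0, 20, n), "basin": rng.integers(0, 10, n)},
            fix_sd={"species": 1e-5, "basin": 1e-5},
        )
        oracle = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert np.allclose(fit.beta, oracle.params.values, rtol=1e-4)

    def test_estimate_within_two_joint_se_of_glm_when_no_heterogeneity(self):
        records = simulate_glmm_records(
            seed=5, sd_species=0.0, sd_country=0.0, sd_basin=0.0,
            n_species=40, n_countries=3, basins_per_country=6,
        )
        fit = fit_occurrence_glmm(records, ModelSpec(predictors=["mpd_z"]))
        X = add_intercept(records[["mpd_z"]])
        oracle = sm.GLM(
            records["presence"].to_numpy(float), X, family=sm.families.Binomial()
        ).fit()
        joint_se = np.hypot(fit.mixed.se, oracle.bse.values)
        assert np.all(np.abs(fit.mixed.beta - oracle.params.values) < 2 * joint_se)

    def test_constant_predictor_is_design_rank_error(self, glmm_records):
        bad = glmm_records.assign(mpd_z=1.0)
        with pytest.raises(DesignError, match="rank"):
            fit_occurrence_glmm(bad, ModelSpec(predictors=["mpd_z"]))

    def test_all_zero_response_rejected(self, glmm_records):
        bad = glmm_records.assign(presence=0)
        with pytest.raises(DesignError, match="all-0"):
            fit_occurrence_glmm(bad, ModelSpec(predictors=["mpd_z"]))

    def test_loglik_never_decreases_with_extra_predictor(self, glmm_records):
        rng = np.random.default_rng(0)
        records = glmm_records.assign(log_area_z=rng.normal(size=len(glmm_records)))
        small = fit_occurrence_glmm(records, ModelSpec(predictors=["mpd_z"]))
        big = fit_occurrence_glmm(
            records, ModelSpec(predictors=["mpd_z", "log_area_z"])
        )
        assert big.mixed.loglik >= small.mixed.loglik - 1e-6

    def test_logit_and_cloglog_agree_in_sign(self, glmm_records):
        logit = fit_occurrence_glmm(glmm_records, ModelSpec(predictors=["mpd_z"]))
        clog = fit_occurrence_glmm(
            glmm_records, ModelSpec(predictors=["mpd_z"], link="cloglog")
        )
        i = logit.mixed.terms.index("mpd_z")
        assert np.sign(logit.mixed.beta[i]) == np.sign(clog.mixed.beta[i])

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_matches_lme4_glmer_reference(self, glmm_records, tmp_path):
        """Independent cross-check of the Laplace fit against lme4."""
        csv = tmp_path / "d.csv"
        glmm_records.to_csv(csv, index=False)
        script = tmp_path / "check.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f"d <- read.csv('{csv}')\n"
            "m <- glmer(presence ~ mpd_z + (1|species) + (1|country) + (1|basin_id),"
            " data=d, family=binomial())\n"
            "co <- summary(m)$coefficients\n"
            "cat(co[,1], co[,2], as.numeric(logLik(m)), sep='\\n')\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        vals = [float(v) for v in out.stdout.split()]
        b0, b1, se0, se1, ll = vals
        fit = fit_occurrence_glmm(glmm_records, ModelSpec(predictors=["mpd_z"]))
        assert fit.mixed.beta[0] == pytest.approx(b0, abs=2e-3)
        assert fit.mixed.beta[1] == pytest.approx(b1, abs=2e-3)
        assert fit.mixed.se[1] == pytest.approx(se1, rel=0.02)
        assert fit.mixed.loglik == pytest.approx(ll, abs=0.05)


class TestNakagawaR2:
    def test_closed_form_logit_example(self):
        r2m, r2c = r2_nakagawa_components(1.0, 1.0, link="logit")
        assert r2m == pytest.approx(1.0 / (2.0 + math.pi**2 / 3.0), abs=1e-12)
        assert r2c == pytest.approx(2.0 / (2.0 + math.pi**2 / 3.0), abs=1e-12)
        assert r2m == pytest.approx(0.189, abs=1e-3)
        assert r2c == pytest.approx(0.378, abs=1e-3)

    def test_cloglog_distribution_variance(self):
        r2m, _ = r2_nakagawa_components(1.0, 0.0, link="cloglog")
        assert r2m == pytest.approx(1.0 / (1.0 + math.pi**2 / 6.0), abs=1e-6)

    def test_zero_random_variance_collapses_marginal_to_conditional(self):
        r2m, r2c = r2_nakagawa_components(1.3, 0.0)
        assert r2m == r2c

    def test_intercept_only_marginal_is_zero(self, glmm_records):
        y = glmm_records["presence"].to_numpy(float)
        X = pd.DataFrame({"(Intercept)": np.ones(len(y))})
        fit = fit_mixed_model(
            y, X, {"species": glmm_records["species"],
                   "basin": glmm_records["basin_id"]},
        )
        r2m, r2c = r2_nakagawa(fit)
        assert r2m == pytest.approx(0.0, abs=1e-12)
        assert 0.0 <= r2m <= r2c <= 1.0

    def test_fit_r2_ordering_invariant(self, glmm_records):
        fit = fit_occurrence_glmm(glmm_records, ModelSpec(predictors=["mpd_z"]))
        assert 0.0 <= fit.r2_marginal <= fit.r2_conditional <= 1.0


class TestVIF:
    def test_orthogonal_predictors(self):
        n = 400
        rng = np.random.default_rng(0)
        t = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        v = vif(t, ["a", "b"])
        assert np.allclose(v, 1.0, atol=0.05)

    def test_correlation_08_closed_form(self):
        # construct exact sample correlation 0.8 via orthogonalization
        rng = np.random.default_rng(1)
        n = 500
        a = rng.normal(size=n)
        e = rng.normal(size=n)
        a = (a - a.mean()) / a.std()
        e = e - e.mean()
        e -= a * (a @ e) / (a @ a)
        e /= e.std()
        b = 0.8 * a + math.sqrt(1 - 0.64) * e
        v = vif(pd.DataFrame({"a": a, "b": b}), ["a", "b"])
        assert np.allclose(v, 1.0 / (1.0 - 0.64), atol=1e-6)

    def test_duplicated_predictor_infinite(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=100)
        v = vif(pd.DataFrame({"a": a, "b": a}), ["a", "b"])
        assert np.isinf(v).all()


class TestChooseLink:
    @pytest.mark.parametrize(
        "fraction,threshold,expected",
        [(0.5, 0.10, "logit"), (0.01, 0.10, "cloglog"), (0.05, 0.0, "logit")],
    )
    def test_policy(self, fraction, threshold, expected):
        n = 1000
        records = pd.DataFrame({"presence": (np.arange(n) < fraction * n).astype(int)})
        assert choose_link(records, threshold) == expected


@pytest.fixture(scope="module")
def sem_fit():
    table, truth = simulate_sem_records(seed=3)
    return fit_sem(table, SEMConfig(diversity="mpd")), truth


class TestSEM:
    def test_product_rule_identity_exact(self, sem_fit):
        fit, _ = sem_fit
        paths = fit.paths.set_index(["from", "to"])["estimate"]
        b_rel = paths[("mpd_z", "presence")]
        for pred in ("native_richness_z", "native_mpd_z"):
            a = paths[(pred, "mpd_z")]
            assert fit.indirect_effects[pred]["estimate"] == a * b_rel

    def test_direct_effects_are_outcome_paths(self, sem_fit):
        fit, _ = sem_fit
        paths = fit.paths.set_index(["from", "to"])["estimate"]
        for pred in ("mpd_z", "native_richness_z", "native_mpd_z"):
            assert fit.direct_effects[pred]["estimate"] == paths[(pred, "presence")]

    def test_programmed_paths_recovered_on_one_replicate(self, sem_fit):
        fit, truth = sem_fit
        eff = fit.indirect_effects["native_richness_z"]
        assert eff["lower"] <= truth["indirect_richness"] <= eff["upper"]

    def test_montecarlo_interval_agrees_with_delta_to_first_order(self):
        table, truth = simulate_sem_records(seed=6)
        delta = fit_sem(table, SEMConfig(diversity="mpd"))
        mc = fit_sem(table, SEMConfig(diversity="mpd"), interval="montecarlo",
                     seed=1)
        d = delta.indirect_effects["native_richness_z"]
        m = mc.indirect_effects["native_richness_z"]
        assert m["estimate"] == d["estimate"]
        assert m["lower"] == pytest.approx(d["lower"], abs=0.03)
        assert m["upper"] == pytest.approx(d["upper"], abs=0.03)

    def test_missing_diversity_column_is_error(self):
        table, _ = simulate_sem_records(seed=4)
        table = table.rename(columns={"mpd_z": "mntd_z"})
        with pytest.raises(ValueError, match="native_mntd_z"):
            fit_sem(table, SEMConfig(diversity="mntd"))

    def test_rows_with_undefined_diversity_dropped_and_counted(self):
        table, _ = simulate_sem_records(seed=5)
        table.loc[:9, "native_mpd_z"] = np.nan
        fit = fit_sem(table, SEMConfig(diversity="mpd"))
        assert fit.rows_dropped == 10
        assert fit.n == len(table) - 10
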