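"""Mixed-model engine: oracles, reductions, invariances, inference."""

import json
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.special import expit
from scipy.stats import norm

from camagree import (
    GlmmOptions,
    GlmmSpec,
    SimulationConfig,
    fit_glmm,
    marginal_loglik_bruteforce,
    predict_latent,
    simulate_cohort,
    wald_from_estimate,
    wald_test_fixed,
)
from camagree.errors import (
    ConvergenceError,
    IntegrationDimensionError,
    SeparationError,
)
from camagree.glmm import PATIENT, PATIENT_METHOD, RATER, GlmmFit


def _small_table(n_pat=3, occ=2, seed=0, si=0.0):
    return simulate_cohort(SimulationConfig(
        n_patients=n_pat, occasions_per_patient=[occ] * n_pat, n_raters=4,
        beta0=-0.3, beta_method=0.8, sigma_patient=1.2, sigma_rater=0.0,
        sigma_interaction=si, simulate_durations=False, seed=seed))


# ---------------------------------------------------------------------------
# degenerate reduction and brute-force oracle


def test_no_random_terms_equals_plain_logistic(small_cohort):
    fit = fit_glmm(small_cohort, GlmmSpec(random_terms=()))
    sm = pytest.importorskip("statsmodels.api")
    X = np.column_stack([
        np.ones(len(small_cohort)),
        (small_cohort["instrument"] == "3DCAM").to_numpy(float)])
    ref = sm.Logit(small_cohort["delirium"].to_numpy(float), X).fit(disp=0)
    assert np.allclose(list(fit.beta.values()), ref.params, atol=1e-6)
    assert abs(fit.loglik - ref.llf) < 1e-6


def test_bruteforce_zero_variance_is_plain_loglik(tiny_table):
    spec = GlmmSpec(random_terms=(PATIENT,))
    beta = np.array([-0.4, 0.9])
    got = marginal_loglik_bruteforce(tiny_table, spec, beta,
                                     {PATIENT: 0.0})
    eta = beta[0] + beta[1] * (tiny_table["instrument"] == "3DCAM")
    y = tiny_table["delirium"].to_numpy(float)
    want = float(np.sum(y * eta - np.logaddexp(0, eta)))
    assert abs(got - want) < 1e-12


def test_bruteforce_matches_independent_quadrature():
    """1 patient, 2 records, s2=1: dense grid vs scipy.integrate.quad."""
    table = pd.DataFrame({
        "patient_id": ["P1"] * 2, "occasion_id": ["O1", "O2"],
        "instrument": ["CAM", "CAM"], "rater_id": ["R1", "R2"],
        "delirium": [1, 0], "acute_change": [0, 0], "inattention": [0, 0],
        "disorganized_thinking": [0, 0], "aloc": [0, 0]})
    spec = GlmmSpec(include_method=False, random_terms=(PATIENT,))
    beta0 = 0.3
    got = marginal_loglik_bruteforce(table, spec, [beta0], {PATIENT: 1.0})

    def integrand(u):
        p = expit(beta0 + u)
        return p * (1 - p) * norm.pdf(u)

    want = np.log(quad(integrand, -12, 12, epsabs=1e-13)[0])
    assert abs(got - want) < 1e-8


def test_bruteforce_label_symmetry(tiny_table):
    """Swapping 0/1 labels and negating beta leaves the loglik unchanged."""
    spec = GlmmSpec(random_terms=(PATIENT,))
    beta = np.array([0.7, -0.4])
    a = marginal_loglik_bruteforce(tiny_table, spec, beta, {PATIENT: 0.8})
    flipped = tiny_table.copy()
    flipped["delirium"] = 1 - flipped["delirium"]
    b = marginal_loglik_bruteforce(flipped, spec, -beta, {PATIENT: 0.8})
    assert abs(a - b) < 1e-10


def test_bruteforce_refuses_nonfactorable_structures(tiny_table):
    with pytest.raises(IntegrationDimensionError):
        marginal_loglik_bruteforce(
            tiny_table, GlmmSpec(random_terms=(PATIENT, RATER)),
            [0.0, 0.0], {PATIENT: 1.0, RATER: 1.0})
    big = _small_table(n_pat=8)
    with pytest.raises(IntegrationDimensionError):
        marginal_loglik_bruteforce(big, GlmmSpec(random_terms=(PATIENT,)),
                                   [0.0, 0.0], {PATIENT: 1.0})


@pytest.mark.parametrize("terms,si", [
    ((PATIENT,), 0.0),
    ((PATIENT, PATIENT_METHOD), 0.6),
])
def test_fit_loglik_matches_bruteforce(terms, si):
    """Adaptive quadrature agrees with dense-grid integration at the
    fitted parameters on tiny patient-factored fixtures."""
    table = _small_table(n_pat=3, occ=2, seed=1, si=si)
    spec = GlmmSpec(random_terms=terms)
    fit = fit_glmm(table, spec, GlmmOptions(quadrature_order=25,
                                            interaction_order=13))
    vc = {t: fit.variance_components[t] if not fit.boundary[t]
          else np.exp(fit.log_sigma[t]) ** 2 for t in terms}
    oracle = marginal_loglik_bruteforce(table, spec,
                                        list(fit.beta.values()), vc)
    assert abs(fit.loglik - oracle) < 1e-3


# ---------------------------------------------------------------------------
# cross-check against an independent mixed-model implementation (lme4)


def _run_lme4(path, formula, nagq):
    script = f"""
    suppressMessages(library(lme4))
    d <- read.delim("{path}")
    d$method <- as.integer(d$instrument == "3DCAM")
    m <- suppressWarnings(glmer({formula}, data=d, family=binomial,
                                nAGQ={nagq}))
    cat(jsonlite::toJSON(list(beta=unname(fixef(m)),
                              vc=unname(unlist(VarCorr(m))),
                              loglik=as.numeric(logLik(m))), digits=12))
    """
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    payload = json.loads(out.stdout)
    payload["loglik"] = payload["loglik"][0]
    return payload


@pytest.fixture(scope="module")
def lme4_fixture(tmp_path_factory):
    from camagree import write_assessments
    table = simulate_cohort(SimulationConfig(
        n_patients=60, occasions_per_patient=[2] * 60, n_raters=6,
        beta0=-0.5, beta_method=0.8, sigma_patient=1.5, sigma_rater=0.4,
        sigma_interaction=0.0, simulate_durations=False, seed=11))
    path = tmp_path_factory.mktemp("lme4") / "fixture.tsv"
    write_assessments(table, path)
    return table, str(path)


def test_agq_matches_lme4(lme4_fixture):
    table, path = lme4_fixture
    ref = _run_lme4(path, "delirium ~ method + (1|patient_id)", nagq=15)
    fit = fit_glmm(table, GlmmSpec(random_terms=(PATIENT,)),
                   GlmmOptions(quadrature_order=15))
    assert np.allclose(list(fit.beta.values()), ref["beta"], atol=2e-3)
    assert abs(fit.variance_components[PATIENT] - ref["vc"][0]) < 5e-3
    assert abs(fit.loglik - ref["loglik"]) < 2e-3


def test_crossed_laplace_matches_lme4(lme4_fixture):
    table, path = lme4_fixture
    ref = _run_lme4(
        path, "delirium ~ method + (1|patient_id) + (1|rater_id)", nagq=1)
    fit = fit_glmm(table, GlmmSpec(random_terms=(PATIENT, RATER)))
    assert np.allclose(list(fit.beta.values()), ref["beta"], atol=2e-2)
    assert abs(fit.loglik - ref["loglik"]) < 2e-2


# ---------------------------------------------------------------------------
# fit contracts


def test_separation_raises_informative_error(tiny_table):
    t = tiny_table.copy()
    t.loc[t["instrument"] == "3DCAM", "delirium"] = 1
    with pytest.raises(SeparationError, match="3DCAM"):
        fit_glmm(t, GlmmSpec(random_terms=(PATIENT,)))


def test_singular_fit_reports_boundary():
    """Perfectly anti-correlated within-patient outcomes push the patient
    variance to its floor; the fit reports 0 with a boundary flag."""
    table = _small_table(n_pat=10, occ=2, seed=4)
    table = table.sort_values(["patient_id", "occasion_id", "instrument"])
    table["delirium"] = np.tile([1, 0], len(table) // 2)
    fit = fit_glmm(table.reset_index(drop=True),
                   GlmmSpec(include_method=False, random_terms=(PATIENT,)))
    assert fit.variance_components[PATIENT] == 0.0
    assert fit.boundary[PATIENT]


def test_relabeling_patients_and_raters_is_invariant(small_cohort):
    spec = GlmmSpec(random_terms=(PATIENT, RATER))
    base = fit_glmm(small_cohort, spec)
    shuffled = small_cohort.copy()
    shuffled["patient_id"] = "Z" + shuffled["patient_id"].str[1:]
    shuffled["rater_id"] = "Q" + shuffled["rater_id"].str[1:]
    shuffled = shuffled.sample(frac=1, random_state=0).reset_index(drop=True)
    other = fit_glmm(shuffled, spec)
    assert np.allclose(list(base.beta.values()),
                       list(other.beta.values()), atol=1e-6)
    for term in spec.random_terms:
        assert abs(base.variance_components[term]
                   - other.variance_components[term]) < 1e-6


def test_converged_implies_gradient_below_tolerance(agreement_fit,
                                                    patient_only_fit):
    for fit in (agreement_fit, patient_only_fit):
        assert fit.converged
        assert fit.gradient_norm < fit.gradient_tol
        assert all(v >= 0 for v in fit.variance_components.values())


# ---------------------------------------------------------------------------
# Wald inference and latent prediction


def test_wald_null_case():
    t = wald_from_estimate(0.0, 1.0)
    assert np.allclose((t.ci_low, t.ci_high), (-1.96, 1.96), atol=1e-3)
    assert t.p_value == 1.0


def test_wald_reproduces_reported_interval_arithmetic():
    """SE back-solved from a symmetric 95% CI reproduces interval and p."""
    t = wald_from_estimate(-0.68, 0.3237)
    assert round(t.ci_low, 2) == -1.31 and round(t.ci_high, 2) == -0.05
    assert abs(t.p_value - 0.036) < 5e-4

    se = (1.74 - 0.71) / (2 * 1.96)
    t2 = wald_from_estimate(1.23, se)
    assert t2.p_value < 0.001


def test_wald_unknown_coefficient(patient_only_fit):
    with pytest.raises(ValueError, match="unknown coefficient"):
        wald_test_fixed(patient_only_fit, "nope")


def test_wald_refuses_nonconverged(patient_only_fit):
    import dataclasses
    broken = dataclasses.replace(patient_only_fit, converged=False)
    with pytest.raises(ConvergenceError):
        wald_test_fixed(broken, "method")


def _fake_fit(beta, eb, patients=("P1",)):
    return GlmmFit(
        spec=GlmmSpec(), beta=beta, beta_cov=np.eye(len(beta)),
        variance_components={}, boundary={}, eb_modes=eb, loglik=0.0,
        converged=True, n_iter=1, gradient_norm=0.0, gradient_tol=1e-3,
        approximation="laplace", n_obs=4, n_dropped=0, patients=patients,
        raters=("R1",), instruments=("3DCAM", "CAM"))


def test_predict_latent_closed_forms():
    fit = _fake_fit({"intercept": 0.0, "method": 0.0},
                    {PATIENT: {"P1": 0.0}})
    assert predict_latent(fit, "P1", "CAM") == (0.0, 0.5)

    fit = _fake_fit({"intercept": -2.0, "method": 1.0},
                    {PATIENT: {"P1": 0.5}, PATIENT_METHOD: {}})
    eta, p = predict_latent(fit, "P1", "3DCAM")
    assert eta == -0.5 and abs(p - 0.3775) < 1e-4

    with pytest.raises(KeyError):
        predict_latent(fit, "P9", "CAM")


def test_large_patient_effect_lifts_both_instruments(small_cohort,
                                                     agreement_fit):
    """The patient with the largest empirical-Bayes intercept sits above
    the cohort mean rate on both instruments."""
    eb = agreement_fit.eb_modes[PATIENT]
    top = max(eb, key=eb.get)
    mean_rate = small_cohort["delirium"].mean()
    for inst in ("CAM", "3DCAM"):
        _, p = predict_latent(agreement_fit, top, inst)
        assert p > mean_rate
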