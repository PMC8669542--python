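"""Latent pairs, Bland-Altman construction, and ratio reporting."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camagree import (
    GlmmOptions,
    GlmmSpec,
    LatentPair,
    SimulationConfig,
    bland_altman,
    extract_latent_pairs,
    feature_agreement,
    probability_ratio,
    ratio_from_log_mean_diff,
    simulate_cohort,
)
from camagree.agreement import LOG_PROBABILITY, PROBABILITY
from camagree.errors import SeparationError
from camagree.glmm import PATIENT, RATER


def _pair(pid, p_cam, p_3d):
    return LatentPair(
        patient_id=pid,
        eta_cam=math.log(p_cam / (1 - p_cam)),
        eta_3dcam=math.log(p_3d / (1 - p_3d)),
        p_cam=p_cam, p_3dcam=p_3d,
        log_p_cam=math.log(p_cam), log_p_3dcam=math.log(p_3d))


def test_constant_model_gives_identical_pairs(patient_only_fit):
    """With all patient modes forced to 0 the latent pair is the same
    closed-form (logistic(b0), logistic(b0+bm)) for every patient."""
    zeroed = dataclasses.replace(
        patient_only_fit,
        beta={"intercept": -1.0, "method": 0.5},
        eb_modes={PATIENT: {p: 0.0 for p in patient_only_fit.patients}})
    pairs = extract_latent_pairs(zeroed)
    assert len(pairs) == len(patient_only_fit.patients)
    for p in pairs:
        assert p.p_cam == pytest.approx(1 / (1 + math.exp(1.0)))
        assert p.p_3dcam == pytest.approx(1 / (1 + math.exp(0.5)))
        assert p.log_p_cam == pytest.approx(math.log(p.p_cam))


def test_pairs_are_invariant_to_patient_relabeling(small_cohort):
    from camagree import fit_glmm
    spec = GlmmSpec(random_terms=(PATIENT,))
    base = fit_glmm(small_cohort, spec)
    relab = small_cohort.copy()
    relab["patient_id"] = "Z" + relab["patient_id"].str[1:]
    other = fit_glmm(relab, spec)
    a = sorted((p.p_cam, p.p_3dcam) for p in extract_latent_pairs(base))
    b = sorted((p.p_cam, p.p_3dcam) for p in extract_latent_pairs(other))
    assert np.allclose(a, b, atol=1e-5)


def test_pairs_require_method_effect(patient_only_fit):
    fit = dataclasses.replace(patient_only_fit, beta={"intercept": 0.0})
    with pytest.raises(ValueError, match="method"):
        extract_latent_pairs(fit)


def test_identical_pairs_degenerate_bland_altman():
    pairs = [_pair(f"P{i}", 0.3, 0.3) for i in range(5)]
    ba = bland_altman(pairs, scale=PROBABILITY)
    assert ba.mean_diff == 0.0
    assert ba.loa == (0.0, 0.0)
    assert len(ba.points) == 5


def test_mean_difference_is_arithmetic_mean_of_log_diffs():
    targets = [-1.0, -1.0, -1.09]
    pairs = [_pair(f"P{i}", 0.2 * math.exp(d), 0.2)
             for i, d in enumerate(targets)]
    ba = bland_altman(pairs, scale=LOG_PROBABILITY)
    assert ba.mean_diff == pytest.approx(np.mean(targets), abs=1e-12)
    assert ba.loa[0] < ba.mean_diff < ba.loa[1]
    assert ba.mean_diff_ci[0] < ba.mean_diff < ba.mean_diff_ci[1]


def test_fewer_than_two_pairs_rejected():
    with pytest.raises(ValueError, match="2 pairs"):
        bland_altman([_pair("P1", 0.4, 0.2)])


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.lists(st.tuples(st.floats(0.02, 0.98), st.floats(0.02, 0.98)),
                min_size=2, max_size=12),
       st.sampled_from([PROBABILITY, LOG_PROBABILITY]))
def test_swapping_instruments_negates_everything(ps, scale):
    pairs = [_pair(f"P{i}", a, b) for i, (a, b) in enumerate(ps)]
    swapped = [_pair(f"P{i}", b, a) for i, (a, b) in enumerate(ps)]
    ba, ba_s = bland_altman(pairs, scale), bland_altman(swapped, scale)
    assert ba_s.mean_diff == pytest.approx(-ba.mean_diff, abs=1e-12)
    assert ba_s.loa[0] == pytest.approx(-ba.loa[1], abs=1e-9)
    for (_, _, d1), (_, _, d2) in zip(ba.points, ba_s.points):
        assert d2 == pytest.approx(-d1, abs=1e-12)
    if scale == LOG_PROBABILITY:
        r, r_s = probability_ratio(ba), probability_ratio(ba_s)
        assert r_s.ratio_unrounded == pytest.approx(
            1 / r.ratio_unrounded, rel=1e-9)


def test_ratio_reporting_convention():
    """Exp-transform with two-decimal rounding and reciprocal-of-rounded
    inverse reproduces the printed reporting arithmetic exactly."""
    r = ratio_from_log_mean_diff(-1.03, (-1.18, -0.88))
    assert r.ratio == 0.36
    assert r.ratio_ci == (0.31, 0.41)
    assert r.inverse_ratio == 2.78
    assert r.inverse_ratio_ci == (2.44, 3.23)

    assert ratio_from_log_mean_diff(0.0, (-0.1, 0.1)).ratio == 1.0
    assert ratio_from_log_mean_diff(1.06, (0.91, 1.21)).ratio == 2.89


def test_ratio_ci_brackets_ratio_property():
    for md in (-2.0, -0.5, 0.0, 0.7):
        r = ratio_from_log_mean_diff(md, (md - 0.3, md + 0.2))
        assert r.ratio_ci_unrounded[0] <= r.ratio_unrounded \
            <= r.ratio_ci_unrounded[1]


def test_probability_scale_refused_for_ratio():
    pairs = [_pair(f"P{i}", 0.6, 0.3) for i in range(3)]
    ba = bland_altman(pairs, scale=PROBABILITY)
    with pytest.raises(ValueError, match="mean_diff directly"):
        probability_ratio(ba)


# ---------------------------------------------------------------------------
# feature-level analyses


@pytest.fixture(scope="module")
def null_feature_cohort():
    """acute_change simulated with no method effect."""
    cfg = SimulationConfig(
        n_patients=150, occasions_per_patient=[2] * 150, n_raters=8,
        beta0=-0.8, beta_method=0.9, sigma_patient=1.5, sigma_rater=0.3,
        sigma_interaction=0.0, seed=21,
        feature_params={"acute_change": (-0.5, 0.0),
                        "inattention": (-1.0, 0.8),
                        "disorganized_thinking": (-1.5, 1.0),
                        "aloc": (-2.0, -0.6)})
    return simulate_cohort(cfg)


def test_null_feature_mean_difference_near_zero(null_feature_cohort):
    fa = feature_agreement(null_feature_cohort, "acute_change",
                           random_terms=(PATIENT, RATER))
    assert fa.scale == PROBABILITY
    assert fa.ratio is None  # probability-scale report carries no ratio
    # the estimated method effect is consistent with the null, and the
    # implied probability-scale shift is small
    assert abs(fa.test.estimate) < 3 * fa.test.std_error
    assert abs(fa.bland_altman.mean_diff) < 0.1


def test_log_scale_feature_reports_ratio(null_feature_cohort):
    fa = feature_agreement(null_feature_cohort, "aloc",
                           random_terms=(PATIENT, RATER))
    assert fa.scale == LOG_PROBABILITY
    assert fa.ratio is not None
    lo, hi = fa.ratio.ratio_ci_unrounded
    assert lo <= fa.ratio.ratio_unrounded <= hi


def test_constant_feature_propagates_named_separation(null_feature_cohort):
    t = null_feature_cohort.copy()
    t["inattention"] = 0
    with pytest.raises(SeparationError, match="inattention"):
        feature_agreement(t, "inattention", random_terms=(PATIENT, RATER))


def test_unknown_feature_rejected(null_feature_cohort):
    with pytest.raises(ValueError, match="unknown feature"):
        feature_agreement(null_feature_cohort, "banana")
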