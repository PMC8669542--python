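"""Latent-variable method agreement: Bland-Altman and probability ratios.

From the fitted two-instrument model, each patient gets a pair of
model-estimated continuous delirium outcomes — one per instrument — built
from the fixed effects and the patient-level empirical-Bayes modes (rater
effects at their population mean).  Those pairs feed a Bland-Altman
analysis on either the probability scale or the natural-log probability
scale; working on per-patient latent summaries is what adjusts the analysis
for repeated assessments of the same patient.

Differences are oriented CAM minus 3D-CAM throughout, so an instrument
that is more often positive than the CAM yields a negative mean difference.
On the log scale, exp(mean difference) is the ratio of positive-result
probabilities, P(CAM+) / P(3DCAM+).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import skew

from .errors import SeparationError
from .glmm import (
    FixedEffectTest,
    GlmmFit,
    GlmmOptions,
    GlmmSpec,
    fit_glmm,
    predict_latent,
    wald_test_fixed,
)
from .records import FEATURES

logger = logging.getLogger(__name__)

PROBABILITY = "probability"
LOG_PROBABILITY = "log_probability"

#: per-response Bland-Altman scale, following the study convention: the
#: altered-level-of-consciousness feature and the overall outcome are
#: analyzed on the log scale, the other features on the probability scale.
DEFAULT_SCALE_POLICY = {
    "delirium": LOG_PROBABILITY,
    "acute_change": PROBABILITY,
    "inattention": PROBABILITY,
    "disorganized_thinking": PROBABILITY,
    "aloc": LOG_PROBABILITY,
}


@dataclass
class LatentPair:
    patient_id: str
    eta_cam: float
    eta_3dcam: float
    p_cam: float
    p_3dcam: float
    log_p_cam: float
    log_p_3dcam: float


@dataclass
class BlandAltmanResult:
    scale: str
    points: list          # (patient_id, average, difference = CAM - 3DCAM)
    mean_diff: float
    mean_diff_ci: tuple
    loa: tuple            # mean_diff -/+ 1.96 * sd_diff
    sd_diff: float

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass
class RatioResult:
    """P(CAM+)/P(3DCAM+) from a log-scale Bland-Altman mean difference.

    Reported values follow the two-decimal rounding convention: the ratio
    and its CI are exp-transformed then rounded, and the inverse ratio is
    the reciprocal of the *rounded* forward values (so a printed 0.36
    inverts to 2.78, not exp(1.03) = 2.80).  The unrounded forward values
    are kept alongside.
    """

    ratio: float
    ratio_ci: tuple
    inverse_ratio: float
    inverse_ratio_ci: tuple
    ratio_unrounded: float
    ratio_ci_unrounded: tuple


def extract_latent_pairs(fit: GlmmFit) -> list[LatentPair]:
    """One (CAM, 3D-CAM) latent pair per patient in the fitted data."""
    if "method" not in fit.beta:
        raise ValueError("fit has no method fixed effect; not an "
                         "agreement model")
    pairs = []
    for pid in fit.patients:
        eta_c, p_c = predict_latent(fit, pid, "CAM")
        eta_d, p_d = predict_latent(fit, pid, "3DCAM")
        pairs.append(LatentPair(
            patient_id=pid, eta_cam=eta_c, eta_3dcam=eta_d,
            p_cam=p_c, p_3dcam=p_d,
            log_p_cam=math.log(p_c), log_p_3dcam=math.log(p_d)))
    return pairs


def _values(pair: LatentPair, scale: str):
    if scale == PROBABILITY:
        return pair.p_cam, pair.p_3dcam
    if scale == LOG_PROBABILITY:
        return pair.log_p_cam, pair.log_p_3dcam
    raise ValueError(f"unknown scale {scale!r}")


def bland_altman(pairs: list[LatentPair],
                 scale: str = LOG_PROBABILITY) -> BlandAltmanResult:
    """Per-patient (average, difference) points with mean difference,
    normal-approximation CI (mean +/- 1.96 SD/sqrt(n)) and 95% limits of
    agreement (mean +/- 1.96 SD)."""
    if len(pairs) < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs (SD of the "
                         "differences is undefined otherwise)")
    points = []
    for pair in pairs:
        a, b = _values(pair, scale)
        points.append((pair.patient_id, (a + b) / 2.0, a - b))
    diffs = np.array([p[2] for p in points])
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    half_ci = 1.96 * sd / np.sqrt(len(diffs))
    return BlandAltmanResult(
        scale=scale, points=points, mean_diff=mean,
        mean_diff_ci=(mean - half_ci, mean + half_ci),
        loa=(mean - 1.96 * sd, mean + 1.96 * sd), sd_diff=sd)


def ratio_from_log_mean_diff(mean_diff: float, ci: tuple) -> RatioResult:
    """Exp-transform reporting arithmetic for a log-scale mean difference."""
    lo, hi = ci
    r, rlo, rhi = (round(math.exp(v), 2) for v in (mean_diff, lo, hi))
    return RatioResult(
        ratio=r, ratio_ci=(rlo, rhi),
        inverse_ratio=round(1.0 / r, 2),
        inverse_ratio_ci=(round(1.0 / rhi, 2), round(1.0 / rlo, 2)),
        ratio_unrounded=math.exp(mean_diff),
        ratio_ci_unrounded=(math.exp(lo), math.exp(hi)))


def probability_ratio(ba: BlandAltmanResult) -> RatioResult:
    """Probability of a positive CAM relative to the 3D-CAM."""
    if ba.scale != LOG_PROBABILITY:
        raise ValueError(
            "probability ratios require a log_probability-scale "
            "Bland-Altman; on the probability scale report mean_diff "
            "directly")
    return ratio_from_log_mean_diff(ba.mean_diff, ba.mean_diff_ci)


@dataclass
class FeatureAgreement:
    feature: str
    scale: str
    test: FixedEffectTest
    bland_altman: BlandAltmanResult
    ratio: RatioResult | None      # only for log-scale analyses
    diff_skewness: float
    log_scale_suggested: bool
    fit: GlmmFit


def feature_agreement(table, feature: str,
                      scale_policy: dict | None = None,
                      random_terms: tuple | None = None,
                      options: GlmmOptions | None = None) -> FeatureAgreement:
    """Agreement analysis (fixed-effect test, Bland-Altman, ratio when on
    the log scale) for one cardinal feature or the overall outcome."""
    if feature not in FEATURES and feature != "delirium":
        raise ValueError(f"unknown feature {feature!r}")
    policy = dict(DEFAULT_SCALE_POLICY)
    if scale_policy:
        policy.update(scale_policy)
    scale = policy[feature]
    spec = GlmmSpec(response=feature, include_method=True,
                    random_terms=random_terms
                    if random_terms is not None
                    else GlmmSpec().random_terms)
    try:
        fit = fit_glmm(table, spec, options)
    except SeparationError as err:
        raise SeparationError(f"feature {feature!r}: {err}") from err
    pairs = extract_latent_pairs(fit)
    ba = bland_altman(pairs, scale=scale)

    # advisory normality check on probability-scale differences; logged,
    # never auto-applied
    prob_diffs = np.array([p.p_cam - p.p_3dcam for p in pairs])
    g1 = float(skew(prob_diffs))
    suggested = abs(g1) > 1.0
    if suggested and scale == PROBABILITY:
        logger.info("feature %s: probability-scale differences are skewed "
                    "(g1=%.2f); a log-scale analysis may be preferable",
                    feature, g1)
    return FeatureAgreement(
        feature=feature, scale=scale,
        test=wald_test_fixed(fit, "method"),
        bland_altman=ba,
        ratio=probability_ratio(ba) if scale == LOG_PROBABILITY else None,
        diff_skewness=g1, log_scale_suggested=suggested, fit=fit)
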