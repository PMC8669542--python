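"""Interrater reliability as a latent-scale intraclass correlation.

From a single-instrument mixed model with patient and rater random
intercepts, the proportion of latent-scale variation attributable to
patients is

    ICC = s2_patient / (s2_patient + s2_rater)

by default, attributing all non-patient variation to raters.  With
``include_residual=True`` the logistic residual variance pi^2/3 is added to
the denominator — the other convention in common use for binary mixed
models; both are exposed because neither is canonical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedStatisticError
from .glmm import PATIENT, RATER, GlmmFit

LOGISTIC_RESIDUAL_VARIANCE = np.pi ** 2 / 3


@dataclass
class IccResult:
    instrument: str
    icc: float
    sigma2_patient: float
    sigma2_rater: float
    includes_residual: bool


def compute_icc(fit: GlmmFit, include_residual: bool = False) -> IccResult:
    """Proportion of latent variation by patients, from a fitted model."""
    vc = fit.variance_components
    if PATIENT not in vc or RATER not in vc:
        raise ValueError("ICC needs a fit with patient and rater random "
                         f"intercepts; fit has {sorted(vc)}")
    s2p, s2r = vc[PATIENT], vc[RATER]
    denom = s2p + s2r + (LOGISTIC_RESIDUAL_VARIANCE if include_residual
                         else 0.0)
    if denom == 0:
        raise UndefinedStatisticError(
            "both variance components are zero; ICC undefined")
    instrument = fit.instruments[0] if len(fit.instruments) == 1 else "both"
    return IccResult(
        instrument=instrument, icc=float(s2p / denom),
        sigma2_patient=float(s2p), sigma2_rater=float(s2r),
        includes_residual=include_residual)
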