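import numpy as np
import pandas as pd
import pytest

from camagree import (
    GlmmOptions,
    GlmmSpec,
    SimulationConfig,
    fit_glmm,
    simulate_cohort,
)
from camagree.glmm import PATIENT, PATIENT_METHOD, RATER


def tiny_frame():
    """Three patients, one occasion each, both instruments, handwritten."""
    rows = []
    for i, (y_cam, y_d3) in enumerate([(0, 1), (1, 1), (0, 0)], start=1):
        for inst, y, rater in [("CAM", y_cam, "R1"), ("3DCAM", y_d3, "R2")]:
            rows.append({
                "patient_id": f"P{i}", "occasion_id": "O1",
                "instrument": inst, "rater_id": rater, "delirium": y,
                "acute_change": y, "inattention": 0,
                "disorganized_thinking": y, "aloc": 0,
                "duration_minutes": 8.0 if inst == "CAM" else 3.0,
            })
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_table():
    return tiny_frame()


@pytest.fixture(scope="session")
def small_cohort():
    """40 patients x 2 occasions, 6 raters, moderate method effect."""
    cfg = SimulationConfig(
        n_patients=40, occasions_per_patient=[2] * 40, n_raters=6,
        beta0=-0.8, beta_method=0.9, sigma_patient=1.5, sigma_rater=0.3,
        sigma_interaction=0.5, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def agreement_fit(small_cohort):
    """Full agreement model (patient + rater + patient-by-method)."""
    return fit_glmm(small_cohort,
                    GlmmSpec(random_terms=(PATIENT, RATER, PATIENT_METHOD)))


@pytest.fixture(scope="session")
def patient_only_fit(small_cohort):
    return fit_glmm(small_cohort, GlmmSpec(random_terms=(PATIENT,)),
                    GlmmOptions(quadrature_order=15))
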