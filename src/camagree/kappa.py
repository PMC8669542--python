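"""Cohen kappa on dichotomized latent pairs, with bootstrap intervals.

The repeated-measures adjustment happens upstream: the mixed model collapses
each patient's repeated assessments into one latent (CAM, 3D-CAM) pair, so
kappa is computed over one binary pair per patient.  Intervals come from a
patient-level bootstrap — either resampling the latent pairs (fast,
default) or resampling patients' raw assessment records and refitting the
model per replicate (slower, propagates fitting uncertainty).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SeparationError, UndefinedStatisticError
from .glmm import GlmmFit, GlmmOptions, GlmmSpec, fit_glmm
from .agreement import LatentPair, extract_latent_pairs

#: kappa interpretation bands, following the "over 0.75 is substantial"
#: phrasing: (exclusive lower bound, label), scanned in order.
DEFAULT_BANDS = ((0.75, "substantial"), (0.40, "moderate"))
DEFAULT_FLOOR_LABEL = "poor"


@dataclass
class KappaResult:
    kappa: float
    ci: tuple | None
    p_observed: float
    p_expected: float
    table2x2: dict      # both_pos, cam_only, d3cam_only, both_neg
    label: str
    n: int


def dichotomize_pairs(pairs: list[LatentPair],
                      threshold: float = 0.5) -> np.ndarray:
    """Map each latent probability to 1 iff p >= threshold.

    Returns an (n, 2) int array with columns (CAM, 3DCAM); a probability
    exactly at the threshold maps to positive.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    out = np.array([[p.p_cam >= threshold, p.p_3dcam >= threshold]
                    for p in pairs], dtype=int)
    return out


def interpret_kappa(kappa: float, bands=DEFAULT_BANDS,
                    floor_label: str = DEFAULT_FLOOR_LABEL) -> str:
    """Label a kappa value from a configurable band table.

    Defaults: > 0.75 substantial; 0.40-0.75 moderate; < 0.40 poor.
    """
    if not -1 <= kappa <= 1:
        raise ValueError("kappa must be in [-1, 1]")
    for lower, label in bands:
        if kappa > lower:
            return label
    if kappa >= bands[-1][0]:  # exactly at the last band edge counts in-band
        return bands[-1][1]
    return floor_label


def cohen_kappa(binary_pairs: np.ndarray) -> KappaResult:
    """Standard 2x2 kappa over one (CAM, 3DCAM) binary pair per patient."""
    bp = np.asarray(binary_pairs, dtype=int)
    if bp.ndim != 2 or bp.shape[1] != 2 or bp.shape[0] < 1:
        raise ValueError("binary_pairs must be an (n>=1, 2) array")
    cam, d3 = bp[:, 0], bp[:, 1]
    n = len(bp)
    a = int(np.sum((cam == 1) & (d3 == 1)))
    b = int(np.sum((cam == 1) & (d3 == 0)))
    c = int(np.sum((cam == 0) & (d3 == 1)))
    d = int(np.sum((cam == 0) & (d3 == 0)))
    p_o = (a + d) / n
    p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / n ** 2
    if p_e >= 1.0:
        raise UndefinedStatisticError(
            "both instruments are constant; chance agreement is 1 and "
            "kappa is undefined")
    kappa = (p_o - p_e) / (1.0 - p_e)
    return KappaResult(
        kappa=float(kappa), ci=None, p_observed=float(p_o),
        p_expected=float(p_e),
        table2x2={"both_pos": a, "cam_only": b, "d3cam_only": c,
                  "both_neg": d},
        label=interpret_kappa(kappa), n=n)


def _percentile_ci(samples: np.ndarray, level: float) -> tuple:
    alpha = (1.0 - level) / 2
    return (float(np.quantile(samples, alpha)),
            float(np.quantile(samples, 1 - alpha)))


def kappa_ci(table: pd.DataFrame | None, fit: GlmmFit,
             method: str = "pair_bootstrap", B: int = 2000,
             level: float = 0.95, threshold: float = 0.5,
             seed: int = 0, options: GlmmOptions | None = None) -> tuple:
    """Percentile bootstrap CI for the latent-pair kappa.

    ``pair_bootstrap`` resamples patients' latent pairs with replacement;
    ``refit_bootstrap`` resamples patients' full assessment records and
    refits the model per replicate (requires ``table``).  Replicates with
    undefined kappa are redrawn, capped at 10*B redraws.  Deterministic
    given ``seed``.
    """
    if B < 200:
        raise ValueError("B must be at least 200")
    rng = np.random.default_rng(seed)
    pairs = extract_latent_pairs(fit)
    n = len(pairs)
    kappas, attempts = [], 0
    if method == "pair_bootstrap":
        bp = dichotomize_pairs(pairs, threshold)
        while len(kappas) < B:
            if attempts >= 10 * B:
                raise UndefinedStatisticError(
                    "too many bootstrap replicates with undefined kappa")
            attempts += 1
            idx = rng.integers(0, n, size=n)
            try:
                kappas.append(cohen_kappa(bp[idx]).kappa)
            except UndefinedStatisticError:
                continue
    elif method == "refit_bootstrap":
        if table is None:
            raise ValueError("refit_bootstrap needs the assessment table")
        by_patient = {pid: grp for pid, grp in table.groupby("patient_id")}
        pids = list(by_patient)
        while len(kappas) < B:
            if attempts >= 10 * B:
                raise UndefinedStatisticError(
                    "too many bootstrap replicates with undefined kappa")
            attempts += 1
            chosen = rng.choice(pids, size=len(pids), replace=True)
            frames = []
            for k, pid in enumerate(chosen):
                g = by_patient[pid].copy()
                g["patient_id"] = f"{pid}#{k}"
                frames.append(g)
            boot = pd.concat(frames, ignore_index=True)
            try:
                bfit = fit_glmm(boot, fit.spec, options)
                bp = dichotomize_pairs(extract_latent_pairs(bfit), threshold)
                kappas.append(cohen_kappa(bp).kappa)
            except (UndefinedStatisticError, SeparationError):
                continue
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return _percentile_ci(np.array(kappas), level)


def kappa_with_ci(table: pd.DataFrame | None, fit: GlmmFit,
                  threshold: float = 0.5, method: str = "pair_bootstrap",
                  B: int = 2000, level: float = 0.95, seed: int = 0,
                  options: GlmmOptions | None = None) -> KappaResult:
    """Convenience wrapper: point estimate plus bootstrap CI."""
    pairs = extract_latent_pairs(fit)
    result = cohen_kappa(dichotomize_pairs(pairs, threshold))
    result.ci = kappa_ci(table, fit, method=method, B=B, level=level,
                         threshold=threshold, seed=seed, options=options)
    return result
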