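"""End-to-end analysis pipeline and consolidated reporting.

``run_pipeline`` executes the full study sequence on one assessment table:
read and validate, pair concurrent administrations, per-instrument
reliability models (ICC), the two-instrument agreement model per response,
latent Bland-Altman / probability ratios, and latent-pair kappa with a
bootstrap interval.  Every intermediate artifact is written to the output
directory as JSON/TSV, plus a MANIFEST recording the configuration and how
far the run got.  Reports are JSON-first with a plain-text rendering.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import records as rec
from .agreement import (
    DEFAULT_SCALE_POLICY,
    LOG_PROBABILITY,
    feature_agreement,
)
from .errors import CamagreeError
from .glmm import PATIENT, PATIENT_METHOD, RATER, GlmmOptions, GlmmSpec, fit_glmm
from .icc import compute_icc
from .kappa import kappa_with_ci

logger = logging.getLogger(__name__)

DEFAULT_RANDOM_TERMS = (PATIENT, RATER, PATIENT_METHOD)


@dataclass
class AnalysisConfig:
    input_path: str
    out_dir: str
    responses: tuple = ("delirium",) + rec.FEATURES
    scale_policy: dict = field(default_factory=lambda: dict(DEFAULT_SCALE_POLICY))
    random_terms: tuple = DEFAULT_RANDOM_TERMS
    include_residual_icc: bool = False
    kappa_threshold: float = 0.5
    ci_method: str = "pair_bootstrap"
    bootstrap_b: int = 2000
    seed: int = 0
    glmm_options: GlmmOptions | None = None

    def __post_init__(self):
        unknown = set(self.responses) - set(rec.RESPONSES)
        if unknown:
            raise ValueError(f"unknown response(s): {sorted(unknown)}")


@dataclass
class StudyReport:
    cohort: rec.CohortSummary
    n_orphans: int
    icc: dict                 # instrument -> IccResult
    agreement: dict           # response -> FeatureAgreement (sans fit)
    kappa: dict               # response -> KappaResult
    skipped: dict             # section -> reason
    provenance: dict


class PipelineError(CamagreeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        d = {}
        for f in dataclasses.fields(obj):
            if f.name in ("fit", "points"):  # fits are too big; points go to TSV
                continue
            d[f.name] = _jsonable(getattr(obj, f.name))
        return d
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True)
                    + "\n")


def _write_points(path: Path, ba) -> None:
    lines = ["patient_id\taverage\tdifference"]
    lines += [f"{pid}\t{avg:.6g}\t{diff:.6g}" for pid, avg, diff in ba.points]
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(config: AnalysisConfig) -> StudyReport:
    """Execute the full analysis; deterministic given ``config.seed``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    completed = []
    manifest = {"config": _jsonable(replace(config, glmm_options=None)),
                "completed_stages": completed, "status": "running"}

    def checkpoint():
        _write_json(out / "MANIFEST.json", manifest)

    stage = "read"
    try:
        table = rec.read_assessments(config.input_path)
        completed.append(stage)

        stage = "summarize"
        cohort = rec.summarize_cohort(table)
        _write_json(out / "cohort_summary.json", cohort)
        completed.append(stage)

        stage = "pair"
        pairing = rec.pair_assessments(table)
        logger.info("%d pairs, %d orphan occasions", len(pairing.pairs),
                    len(pairing.orphans))
        completed.append(stage)

        stage = "interrater_icc"
        icc = {}
        icc_spec = GlmmSpec(response="delirium", include_method=False,
                            random_terms=(PATIENT, RATER))
        for inst in rec.INSTRUMENTS:
            sub = table.loc[table["instrument"] == inst]
            fit = fit_glmm(sub, icc_spec, config.glmm_options)
            logger.info("ICC fit %s: converged=%s loglik=%.3f grad=%.2e",
                        inst, fit.converged, fit.loglik, fit.gradient_norm)
            icc[inst] = compute_icc(fit, config.include_residual_icc)
            _write_json(out / f"icc_{inst}.json", icc[inst])
        completed.append(stage)

        agreement, kappa, skipped = {}, {}, {}
        for resp in config.responses:
            stage = f"agreement:{resp}"
            try:
                fa = feature_agreement(
                    table, resp, scale_policy=config.scale_policy,
                    random_terms=config.random_terms,
                    options=config.glmm_options)
            except CamagreeError as err:
                skipped[resp] = str(err)
                logger.warning("skipping %s: %s", resp, err)
                continue
            fit = fa.fit
            logger.info("agreement fit %s: converged=%s loglik=%.3f "
                        "grad=%.2e", resp, fit.converged, fit.loglik,
                        fit.gradient_norm)
            agreement[resp] = fa
            _write_json(out / f"agreement_{resp}.json", fa)
            _write_points(out / f"ba_points_{resp}.tsv", fa.bland_altman)
            completed.append(stage)

            stage = f"kappa:{resp}"
            kappa[resp] = kappa_with_ci(
                table, fit, threshold=config.kappa_threshold,
                method=config.ci_method, B=config.bootstrap_b,
                seed=config.seed, options=config.glmm_options)
            _write_json(out / f"kappa_{resp}.json", kappa[resp])
            completed.append(stage)

        report = StudyReport(
            cohort=cohort, n_orphans=len(pairing.orphans), icc=icc,
            agreement=agreement, kappa=kappa, skipped=skipped,
            provenance={"package": "camagree", "seed": config.seed,
                        "input": str(config.input_path)})
        _write_json(out / "report.json", report)
        (out / "report.txt").write_text(render_report(report, "text"))
        manifest["status"] = "complete"
        checkpoint()
        return report
    except Exception as err:
        manifest["status"] = f"failed at {stage}"
        checkpoint()
        if isinstance(err, PipelineError):
            raise
        raise PipelineError(stage, err) from err


def render_report(report: StudyReport, format: str = "text") -> str:
    """Render a report as JSON or as a human-readable text summary."""
    if format == "json":
        return json.dumps(_jsonable(report), indent=2, sort_keys=True)
    if format != "text":
        raise ValueError(f"unknown format {format!r}")
    L = []
    c = report.cohort
    L.append("Cohort")
    L.append(f"  {c.n_patients} patients, {c.n_pairs} concurrent assessment "
             f"pairs, {c.n_raters} raters; {report.n_orphans} unpaired "
             "occasions")
    L.append("Interrater reliability (proportion of latent variation by "
             "patients)")
    for inst, r in report.icc.items():
        L.append(f"  {inst}: ICC = {r.icc:.2f} "
                 f"(s2_patient={r.sigma2_patient:.2f}, "
                 f"s2_rater={r.sigma2_rater:.2f})")
    L.append("Method agreement (CAM - 3DCAM)")
    for resp, fa in report.agreement.items():
        t = fa.test
        L.append(f"  {resp}: fixed-effect difference {-t.estimate:.2f} "
                 f"(95% CI, {-t.ci_high:.2f} to {-t.ci_low:.2f}; "
                 f"P = {t.p_value:.3f})")
        ba = fa.bland_altman
        line = (f"    Bland-Altman [{ba.scale}]: mean difference "
                f"{ba.mean_diff:.2f} (95% CI, {ba.mean_diff_ci[0]:.2f} to "
                f"{ba.mean_diff_ci[1]:.2f}); LoA ({ba.loa[0]:.2f}, "
                f"{ba.loa[1]:.2f})")
        L.append(line)
        if fa.ratio is not None:
            r = fa.ratio
            L.append(f"    P(CAM+)/P(3DCAM+) = {r.ratio:.2f} (95% CI, "
                     f"{r.ratio_ci[0]:.2f} to {r.ratio_ci[1]:.2f}); inverse "
                     f"{r.inverse_ratio:.2f} (95% CI, "
                     f"{r.inverse_ratio_ci[0]:.2f} to "
                     f"{r.inverse_ratio_ci[1]:.2f})")
    L.append("Cohen kappa on model-estimated binary pairs")
    for resp, k in report.kappa.items():
        ci = f" (95% CI, {k.ci[0]:.2f}-{k.ci[1]:.2f})" if k.ci else ""
        L.append(f"  {resp}: kappa = {k.kappa:.2f}{ci} -> {k.label}")
    for section, reason in report.skipped.items():
        L.append(f"  [skipped] {section}: {reason}")
    return "\n".join(L) + "\n"
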