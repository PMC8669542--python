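#!/usr/bin/env python
"""Cohen kappa on model-estimated binary pairs, overall and per feature.

Each patient's latent probabilities are dichotomized at 0.5 into one
binary (CAM, 3D-CAM) pair, and kappa with a patient-level bootstrap CI
(B = 2000 pair resamples) is reported with its interpretation label
(> 0.75 substantial; 0.40-0.75 moderate; < 0.40 poor).
"""

import json
from pathlib import Path

from camagree import (
    GlmmSpec,
    fit_glmm,
    kappa_with_ci,
    read_assessments,
)
from camagree.records import FEATURES
from camagree.pipeline import _jsonable

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main():
    table = read_assessments(RESULTS / "cohort.tsv")
    out = {}
    for resp in ("delirium",) + FEATURES:
        fit = fit_glmm(table, GlmmSpec(response=resp))
        res = kappa_with_ci(table, fit, B=2000, seed=SEED)
        out[resp] = _jsonable(res)
        print(f"{resp:>22s}: kappa = {res.kappa:.2f} "
              f"(95% CI, {res.ci[0]:.2f}-{res.ci[1]:.2f}) -> {res.label}")
    (RESULTS / "kappa.json").write_text(json.dumps(out, indent=2) + "\n")


if __name__ == "__main__":
    main()
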