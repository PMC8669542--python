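#!/usr/bin/env python
"""Overall method agreement: fixed-effect contrast, latent Bland-Altman,
probability ratio.

Fits the two-instrument agreement model (patient + rater + patient-by-
method random effects), tests the method fixed effect, builds one latent
(CAM, 3D-CAM) pair per patient, and summarizes the log-scale Bland-Altman
with its exp-transformed probability ratio.  Differences are CAM minus
3D-CAM, so a screening instrument that is more often positive shows up as
a negative mean difference and a ratio below 1.
"""

import json
from pathlib import Path

from camagree import feature_agreement, read_assessments
from camagree.pipeline import _jsonable, _write_points

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    table = read_assessments(RESULTS / "cohort.tsv")
    fa = feature_agreement(table, "delirium")
    t, ba, r = fa.test, fa.bland_altman, fa.ratio
    print(f"fixed-effect difference (CAM - 3DCAM): {-t.estimate:.2f} "
          f"(95% CI, {-t.ci_high:.2f} to {-t.ci_low:.2f}; "
          f"P = {t.p_value:.3f})")
    print(f"Bland-Altman (log scale, {ba.n} patients): mean difference "
          f"{ba.mean_diff:.2f} (95% CI, {ba.mean_diff_ci[0]:.2f} to "
          f"{ba.mean_diff_ci[1]:.2f}); LoA ({ba.loa[0]:.2f}, "
          f"{ba.loa[1]:.2f})")
    print(f"P(CAM+) = {r.ratio:.2f} (95% CI, {r.ratio_ci[0]:.2f} to "
          f"{r.ratio_ci[1]:.2f}) times P(3DCAM+); inversely the 3D-CAM is "
          f"{r.inverse_ratio:.2f} (95% CI, {r.inverse_ratio_ci[0]:.2f} to "
          f"{r.inverse_ratio_ci[1]:.2f}) times as likely to be positive")
    (RESULTS / "method_agreement.json").write_text(
        json.dumps(_jsonable(fa), indent=2) + "\n")
    _write_points(RESULTS / "ba_points_delirium.tsv", ba)


if __name__ == "__main__":
    main()
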