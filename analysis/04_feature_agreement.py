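#!/usr/bin/env python
"""Per-feature agreement for the four cardinal delirium features.

Repeats the agreement analysis for acute change, inattention, disorganized
thinking and altered level of consciousness.  The first three are
summarized on the probability scale (mean difference in latent
probabilities); altered level of consciousness is summarized on the log
scale with an exp-transformed ratio, following the scale policy used for
the overall outcome.
"""

import json
from pathlib import Path

from camagree import feature_agreement, read_assessments
from camagree.records import FEATURES
from camagree.pipeline import _jsonable

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    table = read_assessments(RESULTS / "cohort.tsv")
    out = {}
    for feat in FEATURES:
        fa = feature_agreement(table, feat)
        out[feat] = _jsonable(fa)
        ba = fa.bland_altman
        line = (f"{feat:>22s} [{fa.scale}]: mean diff {ba.mean_diff:+.2f} "
                f"(95% CI, {ba.mean_diff_ci[0]:.2f} to "
                f"{ba.mean_diff_ci[1]:.2f})")
        if fa.ratio is not None:
            line += f"; ratio {fa.ratio.ratio:.2f}"
        print(line)
    (RESULTS / "feature_agreement.json").write_text(
        json.dumps(out, indent=2) + "\n")


if __name__ == "__main__":
    main()
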