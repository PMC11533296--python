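"""Estimate sampling probabilities and inverse-probability weights.

Each sampled control's probability of ever entering the NCC dataset is
computed three ways -- the closed-form Kaplan-Meier-type product over
case risk sets, a logistic regression on censoring time, and a spline
GAM -- then inverted into weights and rescaled so control weights sum to
the cohort's control count.
"""

import numpy as np

from nccvalidate import (
    CohortConfig,
    NCCDesign,
    compute_weights,
    deduplicate,
    replace_orphan_controls,
    sample_ncc,
    simulate_cohort,
)

config = CohortConfig(n_subjects=3000, seed=7)
cohort = simulate_cohort(config)
design = NCCDesign(m=1, seed=1)
sample = replace_orphan_controls(
    deduplicate(sample_ncc(cohort, design), 1), cohort, design, 1
)

n_c = int((cohort["event"] == 0).sum())
for method in ("km", "glm", "gam"):
    w = compute_weights(cohort, sample, design, method=method)
    ctrl = w.table[w.table["role"] == "control"]
    print(
        f"{method}: control p in [{ctrl['p'].min():.3f}, {ctrl['p'].max():.3f}], "
        f"raw weight sum {ctrl['w'].sum():.0f}, "
        f"rescaled sum {ctrl['w_rescaled'].sum():.0f} (cohort controls: {n_c})"
    )
# Every control weight is >= 1 (it stands in for itself and the controls
# that were not sampled); after rescaling the control mass equals the
# cohort control count exactly, so weighted metrics see the cohort's
# case/control balance instead of the distorted ~1:1 NCC balance.
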