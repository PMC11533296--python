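"""Validate a risk model on an NCC sample, weighted vs unweighted.

The same prediction model is evaluated three ways: on the full cohort
(the reference), on the NCC sample with sampling weights, and on the NCC
sample naively.  Weighted metrics track the full cohort; the naive O/E
ratio and PPV are an order of magnitude off because cases make up half
the NCC sample instead of ~5% of the cohort.
"""

import numpy as np

from nccvalidate import (
    CohortConfig,
    NCCDesign,
    c_index,
    calibration_groups,
    calibration_slope,
    compute_weights,
    decision_curve,
    deduplicate,
    harm_to_threshold,
    oe_ratio,
    replace_orphan_controls,
    sample_ncc,
    simulate_cohort,
    threshold_metrics_survival,
)

config = CohortConfig(n_subjects=3000, seed=7)
horizon = config.horizon
cohort = simulate_cohort(config)
design = NCCDesign(m=1, seed=1)
sample = replace_orphan_controls(
    deduplicate(sample_ncc(cohort, design), 1), cohort, design, 1
)
weights = compute_weights(cohort, sample, design)

sub = cohort.set_index("subject_id").loc[sample.records["subject_id"]]
w = weights.vector(sample.records["subject_id"])
unit_ncc = np.ones(len(sub))
unit_full = np.ones(len(cohort))

print(f"{'metric':<12}{'full cohort':>12}{'weighted NCC':>14}{'naive NCC':>12}")
rows = [
    ("c_index", lambda t, e, r, lp, ww: c_index(r, t, e, ww)),
    ("oe_ratio", lambda t, e, r, lp, ww: oe_ratio(t, e, r, ww, horizon)),
    ("slope", lambda t, e, r, lp, ww: calibration_slope(lp, t, e, ww)),
]
for name, fn in rows:
    full = fn(cohort["time"], cohort["event"], cohort["risk"], cohort["lp"], unit_full)
    wgt = fn(sub["time"], sub["event"], sub["risk"], sub["lp"], w)
    naive = fn(sub["time"], sub["event"], sub["risk"], sub["lp"], unit_ncc)
    print(f"{name:<12}{full:>12.3f}{wgt:>14.3f}{naive:>12.3f}")

p_t = 0.05
for label, ww in (("weighted", w), ("naive", unit_ncc)):
    m = threshold_metrics_survival(sub["time"], sub["event"], sub["risk"], ww, p_t, horizon)
    print(f"{label} @ p_t={p_t}: SE={m.se:.2f} SP={m.sp:.2f} PPV={m.ppv:.3f} NPV={m.npv:.3f}")
# The naive PPV is inflated roughly tenfold: half the NCC subjects are
# cases, so a positive prediction looks far better than it is.

p_t = harm_to_threshold(4.0)  # missing an event 4x worse than overtreating
curve = decision_curve(
    sub["time"], sub["event"], sub["risk"], w,
    thresholds=sorted([0.02, 0.04, 0.06, p_t]), horizon=horizon,
)
print("\nweighted decision curve (net benefit per 1 subject):")
print(curve.table.round(4).to_string(index=False))

print("\nweighted calibration groups (observed vs predicted):")
print(
    calibration_groups(sub["risk"], sub["time"], sub["event"], w, 5, horizon)
    .round(4)
    .to_string(index=False)
)
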