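"""Replicate-level demonstration: weighted metrics are unbiased, naive
metrics are not, and matching on a prediction-correlated variable makes
the naive bias worse.

Draws 20 NCC replicates per design (kept small so the script runs in
about half a minute; the test suite runs the full 50) and tabulates the
replicate-mean weighted and unweighted metrics against the full-cohort
reference.
"""

import pandas as pd

from nccvalidate import CohortConfig, ExperimentConfig, run_experiment

config = ExperimentConfig(
    cohort=CohortConfig(n_subjects=3000, seed=0),
    R=20,
    weight_methods=["km"],
    seed=0,
)
report = run_experiment(config)

pd.set_option("display.width", 160)
core = report.summary[report.summary["metric"].isin(["c_index", "oe_ratio", "ppv"])]
table = core.pivot_table(index=["metric", "design"], columns="method",
                         values=["mean"]).round(3)
print("full-cohort reference:",
      {k: round(v, 3) for k, v in report.full_cohort.items()
       if k in ("c_index", "oe_ratio", "ppv")})
print(table)
# Reading: the km column sits on the full-cohort value in every design;
# the unweighted column shows O/E and PPV roughly 10x too high (cases are
# over-represented ~10-fold) and a C-index biased low, most severely in
# the risk-matched design where matching removes part of the model's
# discrimination from the sample.
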