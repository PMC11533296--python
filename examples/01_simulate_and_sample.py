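"""Simulate a full cohort and draw a nested case-control sample from it.

The cohort has a rare outcome (~5% cumulative incidence at 10 years),
three risk factors, and censoring that removes sex = 0 subjects faster
than sex = 1 subjects -- the mechanism that makes naive analysis of the
NCC subsample biased.  Incidence density sampling then picks one control
per case from the case's risk set, duplicates are collapsed to one
record per subject, and orphaned matched sets are topped up while the
inverse-probability weight sum stays close to the cohort size.
"""

import numpy as np

from nccvalidate import (
    CohortConfig,
    NCCDesign,
    cohort_summary,
    deduplicate,
    replace_orphan_controls,
    sample_ncc,
    simulate_cohort,
    validate_sample,
)

config = CohortConfig(n_subjects=3000, seed=7)
cohort = simulate_cohort(config)
summary = cohort_summary(cohort, config.horizon)
print("full cohort:", summary)
# n, case/control counts and the Kaplan-Meier cumulative incidence at the
# 10-year horizon -- the targets the weighted NCC analysis must recover.

design = NCCDesign(m=1, seed=1)
sample = sample_ncc(cohort, design)
print("sampled records (pre-deduplication):", len(sample.records))

sample = deduplicate(sample, seed=1)
sample = replace_orphan_controls(sample, cohort, design, seed=1)
validate_sample(sample, cohort)
roles = sample.records["role"].value_counts().to_dict()
print("NCC dataset after deduplication + orphan replacement:", roles)
# Roughly one control per case: the NCC dataset is ~10x smaller than the
# cohort, with every case and a time-matched subset of controls.
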