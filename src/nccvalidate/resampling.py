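"""Matched-set-preserving bootstrap and cross-validation for NCC data.

The NCC design is stratified: every case is tied to its sampled controls
at least through follow-up time.  Internal validation must therefore
resample whole matched sets, never individual subjects, and evaluate the
model with the same sampling weights inside each replicate or fold.
Weights are not re-estimated within replicates by default (subjects carry
their original weights; re-estimation can be supplied via
``weight_fn``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import NCCSample
from .weights import Weights


def _set_ids(sample: NCCSample) -> np.ndarray:
    if not sample.deduplicated:
        raise ValueError("resampling expects a deduplicated sample")
    return np.unique(sample.records["matched_set_id"].to_numpy())


def paired_bootstrap(
    sample: NCCSample, B: int, seed: int | np.random.Generator = 0
) -> list[np.ndarray]:
    """Draw ``B`` bootstrap replicates of matched-set ids, each sampling
    the original number of sets with replacement.  Sets drawn several
    times contribute their subjects that many times, weights unchanged."""
    sets = _set_ids(sample)
    if len(sets) < 2:
        raise ValueError("need at least 2 matched sets to bootstrap")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [rng.choice(sets, size=len(sets), replace=True) for _ in range(B)]


def paired_cv_folds(
    sample: NCCSample, k: int, seed: int | np.random.Generator = 0
) -> dict:
    """Assign each matched set wholly to one of ``k`` folds (sizes differ
    by at most one set).  Returns a dict set_id -> fold index."""
    sets = _set_ids(sample)
    if not 2 <= k <= len(sets):
        raise ValueError("k must be between 2 and the number of matched sets")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(sets)
    return {int(s): i % k for i, s in enumerate(perm)}


def replicate_frame(
    sample: NCCSample, weights: Weights, set_draw: np.ndarray
) -> pd.DataFrame:
    """Materialize one bootstrap replicate: records of the drawn sets
    (with multiplicity) joined with their subjects' weights."""
    rec = sample.records.merge(
        weights.table[["subject_id", "w_rescaled"]], on="subject_id", how="left"
    )
    by_set = rec.groupby("matched_set_id").indices
    idx = np.concatenate([by_set[s] for s in set_draw])
    return rec.iloc[idx].reset_index(drop=True)


def bootstrap_ci(
    metric_fn,
    sample: NCCSample,
    weights: Weights,
    B: int = 200,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
    weight_fn=None,
) -> tuple[float, float, float]:
    """Percentile bootstrap confidence interval of a weighted metric.

    ``metric_fn(df)`` receives a replicate DataFrame (sample records plus
    a ``w_rescaled`` column) and returns a scalar; it is also evaluated
    on the original sample for the point estimate.  ``weight_fn(df)``
    may replace the carried-over weights inside each replicate.
    Raises if the metric is undefined in more than half the replicates.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = paired_bootstrap(sample, B, rng)

    full = sample.records.merge(
        weights.table[["subject_id", "w_rescaled"]], on="subject_id", how="left"
    )
    estimate = float(metric_fn(full))

    by_set = full.groupby("matched_set_id").indices
    values = []
    for d in draws:
        idx = np.concatenate([by_set[s] for s in d])
        df = full.iloc[idx].reset_index(drop=True)
        if weight_fn is not None:
            df = weight_fn(df)
        try:
            v = float(metric_fn(df))
        except (ValueError, ZeroDivisionError):
            v = float("nan")
        values.append(v)
    values = np.asarray(values)
    ok = np.isfinite(values)
    if ok.sum() < 0.5 * B:
        raise ValueError("metric undefined in more than half the bootstrap replicates")
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(values[ok], [alpha, 1.0 - alpha])
    return estimate, float(lower), float(upper)
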