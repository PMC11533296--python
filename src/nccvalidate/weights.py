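"""Sampling probabilities and inverse-probability weights for NCC data.

A subject's weight is the inverse of its probability of ending up in the
NCC dataset.  Cases are sampled with probability 1 in a typical NCC (or
with the sampled case fraction in an atypical one).  A control's inclusion
probability can be computed three ways:

``km``
    the closed-form product over cases,
    ``p_i = 1 - prod_j (1 - m / (n_j(t_j) - 1))`` restricted to the cases
    for which control *i* was eligible, where ``n_j(t_j) - 1`` is the size
    of case *j*'s (matched) risk set excluding the case itself;
``glm``
    a logistic regression of the sampled-as-control indicator on censoring
    time and matching variables, fitted to all non-cases in the cohort;
``gam``
    the same with a penalized spline in censoring time.

Raw weights ``w = 1/p`` generally do not sum to the cohort size, so
control weights are rescaled to sum to the cohort's control count ``n_c``;
case weights are left untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import CASE, CONTROL, NCCDesign, NCCSample

PROB_CLIP = (1e-6, 1.0)


@dataclass
class SamplingProbabilities:
    """Per-subject inclusion probabilities for a (deduplicated) NCC sample.

    ``table`` has columns ``subject_id``, ``role``, ``p``.  All cases
    share one value of ``p``.
    """

    table: pd.DataFrame
    method: str


@dataclass
class Weights:
    """Raw (``w``) and control-rescaled (``w_rescaled``) inverse
    probability weights; ``n_c`` is the cohort's control count."""

    table: pd.DataFrame  # subject_id, role, p, w, w_rescaled
    n_c: int
    method: str

    def vector(self, subject_ids, rescaled: bool = True) -> np.ndarray:
        col = "w_rescaled" if rescaled else "w"
        lookup = self.table.set_index("subject_id")[col]
        return lookup.loc[np.asarray(subject_ids)].to_numpy()


def case_probabilities(n_cases_sampled: int, n_cases_total: int) -> float:
    """Sampling probability shared by all cases: the fraction of cohort
    cases included in the NCC dataset (1 in a typical NCC)."""
    if n_cases_sampled <= 0:
        raise ValueError("no sampled cases")
    if n_cases_sampled > n_cases_total:
        raise ValueError("more sampled cases than cohort cases")
    return n_cases_sampled / n_cases_total


def _sample_frames(cohort: pd.DataFrame, sample: NCCSample):
    rec = sample.records
    if not sample.deduplicated:
        raise ValueError("weights expect a deduplicated sample")
    case_ids = rec.loc[rec["role"] == CASE, "subject_id"].to_numpy()
    control_ids = rec.loc[rec["role"] == CONTROL, "subject_id"].to_numpy()
    cohort_idx = cohort.set_index("subject_id")
    return rec, case_ids, control_ids, cohort_idx


def km_inclusion_probabilities(
    cohort: pd.DataFrame,
    design: NCCDesign,
    subject_ids,
    triggering_case_ids=None,
) -> np.ndarray:
    """Closed-form probability that each subject in ``subject_ids`` is
    sampled as a control for at least one case, the product over cases of
    one minus the per-set selection fraction ``m / (n_j(t_j) - 1)``.

    ``triggering_case_ids`` restricts the product to the cases that
    actually triggered risk sets (needed when only a fraction of cases
    was sampled); default: all cohort cases.  Factors are clamped at zero
    when ``m`` reaches the risk-set size (the control is then selected
    with certainty for that case).  Subjects never eligible for any case
    get probability 0.
    """
    events = cohort["event"].to_numpy().astype(int)
    ids = cohort["subject_id"].to_numpy()
    times = cohort["time"].to_numpy().astype(float)
    subject_ids = np.asarray(subject_ids)

    if triggering_case_ids is None:
        triggering = events == 1
    else:
        triggering = np.isin(ids, np.asarray(triggering_case_ids)) & (events == 1)
    trig_ids = ids[triggering]
    trig_times = times[triggering]
    order = np.lexsort((trig_ids, trig_times))
    trig_ids, trig_times = trig_ids[order], trig_times[order]

    match_cols = [cohort[v].to_numpy() for v in design.matching_vars]
    pos = pd.Index(ids).get_indexer(subject_ids)
    sub_times = times[pos]
    sub_match = [col[pos] for col in match_cols]

    log_not_sampled = np.zeros(len(subject_ids))
    cohort_pos = {s: k for k, s in enumerate(ids)}
    for cid, t_j in zip(trig_ids, trig_times):
        k = cohort_pos[cid]
        elig = (times >= t_j) & (ids != cid)
        for col in match_cols:
            elig &= col == col[k]
        size = int(elig.sum())
        if size == 0:
            continue
        sub_elig = (sub_times >= t_j) & (subject_ids != cid)
        for col, cm in zip(match_cols, sub_match):
            sub_elig &= cm == col[k]
        frac = min(design.m / size, 1.0)
        if frac >= 1.0:
            log_not_sampled[sub_elig] = -np.inf
        else:
            log_not_sampled[sub_elig] += np.log1p(-frac)
    return 1.0 - np.exp(log_not_sampled)


def km_probabilities(
    cohort: pd.DataFrame, sample: NCCSample, design: NCCDesign
) -> SamplingProbabilities:
    """Closed-form inclusion probabilities under incidence density
    sampling.

    The product runs over all cohort cases when every case triggered a
    risk set (typical NCC); under ``case_fraction < 1`` only the sampled
    cases did, so the product is restricted to them.
    """
    rec, case_ids, control_ids, cohort_idx = _sample_frames(cohort, sample)

    trig = case_ids if design.case_fraction < 1.0 else None
    p_control = km_inclusion_probabilities(cohort, design, control_ids, trig)

    if (p_control == 0).any():
        bad = control_ids[p_control == 0].tolist()
        raise ValueError(
            f"sampled controls never eligible for any case (design/sample "
            f"mismatch?): {bad}"
        )
    # a control must at least have been eligible for its own set
    own_case = rec[rec["role"] == CASE].set_index("matched_set_id")["subject_id"]
    ctrl_rec = rec[rec["role"] == CONTROL]
    for _, row in ctrl_rec.iterrows():
        if cohort_idx.loc[row["subject_id"], "time"] < row["sampling_time"]:
            raise ValueError(
                f"control {row['subject_id']!r} not eligible for its own "
                f"matched set {row['matched_set_id']}"
            )
        if design.matching_vars:
            case_sid = own_case.loc[row["matched_set_id"]]
            for var in design.matching_vars:
                if cohort_idx.loc[row["subject_id"], var] != cohort_idx.loc[case_sid, var]:
                    raise ValueError(
                        f"control {row['subject_id']!r} violates matching in "
                        f"set {row['matched_set_id']}"
                    )

    p_case = case_probabilities(len(case_ids), int(cohort["event"].sum()))
    return _assemble(rec, control_ids, p_control, p_case, "km")


def _assemble(rec, control_ids, p_control, p_case, method) -> SamplingProbabilities:
    p_map = dict(zip(control_ids, p_control))
    table = rec[["subject_id", "role"]].copy()
    table["p"] = [
        p_case if role == CASE else p_map[sid]
        for sid, role in zip(table["subject_id"], table["role"])
    ]
    return SamplingProbabilities(table.reset_index(drop=True), method)


def _model_design(cohort_controls: pd.DataFrame, matching_vars) -> pd.DataFrame:
    X = pd.DataFrame({"time": cohort_controls["time"].to_numpy()},
                     index=cohort_controls.index)
    for var in matching_vars:
        dummies = pd.get_dummies(
            cohort_controls[var], prefix=f"match_{var}", drop_first=True, dtype=float
        )
        X = pd.concat([X, dummies], axis=1)
    return X


def glm_probabilities(
    cohort: pd.DataFrame,
    sample: NCCSample,
    design: NCCDesign,
    clip: tuple = PROB_CLIP,
) -> SamplingProbabilities:
    """Model-based inclusion probabilities from a logistic regression of
    the sampled-as-control indicator on censoring time (and matching
    variables), fitted to all non-cases in the full cohort."""
    import statsmodels.api as sm

    rec, case_ids, control_ids, cohort_idx = _sample_frames(cohort, sample)
    non_cases = cohort[cohort["event"] == 0]
    y = non_cases["subject_id"].isin(control_ids).to_numpy().astype(float)
    X = sm.add_constant(_model_design(non_cases, design.matching_vars))
    try:
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        if not np.all(np.isfinite(fit.params)):
            raise ValueError("non-finite coefficients")
    except Exception as err:  # perfect separation, convergence failure
        raise ValueError(
            "logistic sampling-probability model failed to fit "
            f"({err}); consider method='km'"
        ) from err

    ctrl_rows = cohort_idx.loc[control_ids].reset_index()
    Xp = sm.add_constant(_model_design(ctrl_rows, design.matching_vars), has_constant="add")
    Xp = Xp.reindex(columns=X.columns, fill_value=0.0)
    p_control = np.clip(fit.predict(Xp), *clip)
    p_case = case_probabilities(len(case_ids), int(cohort["event"].sum()))
    return _assemble(rec, control_ids, p_control, p_case, "glm")


def gam_probabilities(
    cohort: pd.DataFrame,
    sample: NCCSample,
    design: NCCDesign,
    clip: tuple = PROB_CLIP,
    df: int = 5,
    degree: int = 3,
) -> SamplingProbabilities:
    """As :func:`glm_probabilities` with a penalized B-spline in
    censoring time instead of a linear term."""
    import statsmodels.api as sm
    from statsmodels.gam.api import BSplines, GLMGam

    rec, case_ids, control_ids, cohort_idx = _sample_frames(cohort, sample)
    non_cases = cohort[cohort["event"] == 0]
    y = non_cases["subject_id"].isin(control_ids).to_numpy().astype(float)

    t = non_cases["time"].to_numpy().reshape(-1, 1)
    smoother = BSplines(t, df=[df], degree=[degree])
    X = _model_design(non_cases, design.matching_vars).drop(columns="time")
    X.insert(0, "const", 1.0)
    try:
        fit = GLMGam(y, exog=np.asarray(X, dtype=float), smoother=smoother,
                     family=sm.families.Binomial()).fit()
    except Exception as err:
        raise ValueError(
            "GAM sampling-probability model failed to fit "
            f"({err}); consider method='km'"
        ) from err

    ctrl_rows = cohort_idx.loc[control_ids].reset_index()
    tp = np.clip(ctrl_rows["time"].to_numpy(), t.min(), t.max()).reshape(-1, 1)
    Xp = _model_design(ctrl_rows, design.matching_vars).drop(columns="time")
    Xp.insert(0, "const", 1.0)
    Xp = Xp.reindex(columns=X.columns, fill_value=0.0)
    p_control = np.clip(
        fit.predict(np.asarray(Xp, dtype=float), exog_smooth=tp), *clip
    )
    p_case = case_probabilities(len(case_ids), int(cohort["event"].sum()))
    return _assemble(rec, control_ids, p_control, p_case, "gam")


def invert_and_rescale(
    probs: SamplingProbabilities,
    n_c: int,
    rescale: bool = True,
    truncate: tuple | None = None,
) -> Weights:
    """Invert probabilities into weights (``w = 1/p``) and rescale the
    control weights to sum to the cohort control count ``n_c``.

    Case weights are never rescaled.  ``truncate=(lo, hi)`` winsorizes
    raw control weights before rescaling (off by default).
    """
    table = probs.table.copy()
    if (table["p"] <= 0).any():
        bad = table.loc[table["p"] <= 0, "subject_id"].tolist()
        raise ValueError(f"zero sampling probability for subjects {bad}")
    table["w"] = 1.0 / table["p"]
    is_control = table["role"] == CONTROL
    if truncate is not None:
        table.loc[is_control, "w"] = table.loc[is_control, "w"].clip(*truncate)
    table["w_rescaled"] = table["w"]
    if rescale and is_control.any():
        total = table.loc[is_control, "w"].sum()
        table.loc[is_control, "w_rescaled"] = table.loc[is_control, "w"] * (n_c / total)
    return Weights(table, n_c=n_c, method=probs.method)


_METHODS = {"km": km_probabilities, "glm": glm_probabilities, "gam": gam_probabilities}


def compute_weights(
    cohort: pd.DataFrame,
    sample: NCCSample,
    design: NCCDesign,
    method: str = "km",
    rescale: bool = True,
    truncate: tuple | None = None,
) -> Weights:
    """Probabilities + inversion + rescaling in one call."""
    if method not in _METHODS:
        raise ValueError(f"unknown weight method {method!r}")
    probs = _METHODS[method](cohort, sample, design)
    n_c = int((cohort["event"] == 0).sum())
    return invert_and_rescale(probs, n_c, rescale=rescale, truncate=truncate)


def write_weights(weights: Weights, path, sep: str = ",") -> None:
    out = weights.table.copy()
    out["method"] = weights.method
    out.to_csv(path, sep=sep, index=False)
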