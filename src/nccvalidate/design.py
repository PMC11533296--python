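"""Incidence density sampling of nested case-control (NCC) datasets.

For every case, the subjects still at risk at that case's event time (its
*risk set*, optionally restricted to exact matches on categorical matching
variables) are identified and ``m`` of them are drawn uniformly without
replacement.  Future cases are eligible as controls before their own event;
the same subject can be drawn in several risk sets.  :func:`deduplicate`
then keeps one record per subject (the case record if the subject is ever a
case, otherwise one uniformly chosen control record), and
:func:`replace_orphan_controls` tops up matched sets that lost their only
control to deduplication.

Eligibility uses ``time >= t_j`` -- a subject censored exactly at the
case's event time is at risk -- and excludes the case itself, so the size
of a risk set is the at-risk count minus one.  The sampling-probability
formulas in :mod:`nccvalidate.weights` rely on exactly this rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"


@dataclass
class NCCDesign:
    """Sampling plan: ``m`` controls per case, optional exact matching,
    and the fraction of cohort cases included (1.0 for a typical NCC)."""

    m: int = 1
    matching_vars: list[str] = field(default_factory=list)
    case_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0.0 < self.case_fraction <= 1.0:
            raise ValueError("case_fraction must be in (0, 1]")


@dataclass
class NCCSample:
    """Sampled records: one row per (subject, matched set) membership.

    ``records`` columns: ``subject_id``, ``role`` (case/control),
    ``matched_set_id``, ``sampling_time`` (the set's case event time).
    Before deduplication a subject may appear in several rows.
    """

    records: pd.DataFrame
    deduplicated: bool = False
    m: int = 1
    matching_vars: list[str] = field(default_factory=list)
    case_fraction: float = 1.0

    @property
    def subject_ids(self) -> np.ndarray:
        return self.records["subject_id"].to_numpy()

    def n_sets(self) -> int:
        return self.records["matched_set_id"].nunique()


def risk_set(cohort: pd.DataFrame, case_id, matching_vars=()) -> np.ndarray:
    """Subject ids eligible as controls for ``case_id``: still under
    follow-up at the case's event time, matching exactly on
    ``matching_vars``, excluding the case itself."""
    row = cohort.loc[cohort["subject_id"] == case_id]
    if len(row) != 1 or int(row["event"].iloc[0]) != 1:
        raise ValueError(f"subject {case_id!r} is not a case in this cohort")
    t_j = float(row["time"].iloc[0])
    eligible = (cohort["time"].to_numpy() >= t_j) & (
        cohort["subject_id"].to_numpy() != case_id
    )
    for var in matching_vars:
        eligible &= cohort[var].to_numpy() == row[var].iloc[0]
    return cohort["subject_id"].to_numpy()[eligible]


class NCCSampler:
    """Draws NCC samples from a fixed cohort under a fixed design.

    Risk sets depend only on the cohort and the matching variables, so
    they are computed once at construction; :meth:`draw` is then cheap,
    which matters for Monte-Carlo checks that repeat the sampling
    thousands of times.  Cases are processed in ascending event time,
    ties broken by subject id.
    """

    def __init__(self, cohort: pd.DataFrame, design: NCCDesign):
        if cohort["subject_id"].duplicated().any():
            raise ValueError("duplicate subject_id in cohort")
        self.cohort = cohort
        self.design = design

        events = cohort["event"].to_numpy().astype(int)
        if events.sum() == 0:
            raise ValueError("cohort contains no cases")
        ids = cohort["subject_id"].to_numpy()
        times = cohort["time"].to_numpy().astype(float)

        case_mask = events == 1
        order = np.lexsort((ids[case_mask], times[case_mask]))
        self.case_ids = ids[case_mask][order]
        self.case_times = times[case_mask][order]

        match_cols = [cohort[v].to_numpy() for v in design.matching_vars]
        self._risk_sets: list[np.ndarray] = []
        for cid, t_j in zip(self.case_ids, self.case_times):
            eligible = (times >= t_j) & (ids != cid)
            k = np.flatnonzero(case_mask & (ids == cid))[0]
            for col in match_cols:
                eligible &= col == col[k]
            self._risk_sets.append(ids[eligible])

    def risk_set_sizes(self) -> dict:
        """Map case id -> size of its (matched) risk set."""
        return {cid: len(rs) for cid, rs in zip(self.case_ids, self._risk_sets)}

    def draw(self, rng: np.random.Generator | int | None = None) -> NCCSample:
        design = self.design
        if rng is None:
            rng = np.random.default_rng(design.seed)
        elif not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)

        n_cases = len(self.case_ids)
        if design.case_fraction < 1.0:
            n_keep = max(1, int(round(design.case_fraction * n_cases)))
            keep = np.sort(rng.choice(n_cases, size=n_keep, replace=False))
        else:
            keep = np.arange(n_cases)

        sub_ids, roles, set_ids, samp_times = [], [], [], []
        for set_id, j in enumerate(keep):
            cid = self.case_ids[j]
            t_j = self.case_times[j]
            rs = self._risk_sets[j]
            sub_ids.append(cid)
            roles.append(CASE)
            set_ids.append(set_id)
            samp_times.append(t_j)
            if len(rs) == 0:
                warnings.warn(
                    f"empty risk set for case {cid!r}; set emitted with case only",
                    stacklevel=2,
                )
                continue
            n_draw = min(design.m, len(rs))
            chosen = rng.choice(rs, size=n_draw, replace=False)
            sub_ids.extend(chosen.tolist())
            roles.extend([CONTROL] * n_draw)
            set_ids.extend([set_id] * n_draw)
            samp_times.extend([t_j] * n_draw)

        records = pd.DataFrame(
            {
                "subject_id": sub_ids,
                "role": roles,
                "matched_set_id": set_ids,
                "sampling_time": samp_times,
            }
        )
        return NCCSample(
            records,
            deduplicated=False,
            m=design.m,
            matching_vars=list(design.matching_vars),
            case_fraction=design.case_fraction,
        )


def sample_ncc(cohort: pd.DataFrame, design: NCCDesign) -> NCCSample:
    """One NCC draw; see :class:`NCCSampler` for repeated draws."""
    return NCCSampler(cohort, design).draw()


def deduplicate(sample: NCCSample, seed: int | np.random.Generator = 0) -> NCCSample:
    """Keep one record per subject: the case record for subjects ever
    selected as cases, otherwise one uniformly chosen control record."""
    if sample.deduplicated:
        raise ValueError("sample is already deduplicated")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    rec = sample.records
    keep_idx = []
    # sort groups by subject for determinism; choice resolves multi-control subjects
    for _, grp in rec.groupby("subject_id", sort=True):
        case_rows = grp.index[grp["role"] == CASE]
        if len(case_rows):
            keep_idx.append(case_rows[0])
        elif len(grp) == 1:
            keep_idx.append(grp.index[0])
        else:
            keep_idx.append(rng.choice(grp.index.to_numpy()))
    out = rec.loc[sorted(keep_idx)].reset_index(drop=True)
    return replace(sample, records=out, deduplicated=True)


def replace_orphan_controls(
    sample: NCCSample,
    cohort: pd.DataFrame,
    design: NCCDesign,
    seed: int | np.random.Generator = 0,
    balance_weight_sum: bool = True,
) -> NCCSample:
    """Offer one replacement control to each matched set left control-less
    by deduplication, drawn from the case's matched risk set among
    subjects not already in the sample.

    With ``balance_weight_sum`` (default) a replacement is accepted only
    if it moves the raw Kaplan-Meier weight sum of the sample closer to
    the cohort size.  Deduplication removes a subject from the control
    pool only when it was claimed as a case, so blanket replacement adds
    more inverse-probability mass than was lost and inflates the weight
    sum (replacements are extra draws the closed-form probabilities do
    not account for); the guard keeps the sample representative of the
    cohort.  ``balance_weight_sum=False`` replaces unconditionally.
    Exhausted risk sets leave the set unchanged with a warning.
    """
    if not sample.deduplicated:
        raise ValueError("replace_orphan_controls expects a deduplicated sample")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    rec = sample.records
    in_sample = set(rec["subject_id"])
    has_control = set(rec.loc[rec["role"] == CONTROL, "matched_set_id"])
    case_rows = rec[rec["role"] == CASE].sort_values("matched_set_id")

    if balance_weight_sum:
        # circular at module level: weights builds on design's sample types
        from .weights import case_probabilities, km_inclusion_probabilities

        trig = (
            case_rows["subject_id"].to_numpy() if design.case_fraction < 1.0 else None
        )
        ctrl_ids = rec.loc[rec["role"] == CONTROL, "subject_id"].to_numpy()
        p_ctrl = km_inclusion_probabilities(cohort, design, ctrl_ids, trig)
        w_case = 1.0 / case_probabilities(
            len(case_rows), int(cohort["event"].sum())
        )
        total = len(case_rows) * w_case + float((1.0 / p_ctrl).sum())
        target = float(len(cohort))

    new_rows = []
    for _, case_row in case_rows.iterrows():
        set_id = case_row["matched_set_id"]
        if set_id in has_control:
            continue
        candidates = [
            s
            for s in risk_set(cohort, case_row["subject_id"], design.matching_vars)
            if s not in in_sample
        ]
        if not candidates:
            warnings.warn(
                f"no replacement control available for matched set {set_id}",
                stacklevel=2,
            )
            continue
        chosen = rng.choice(np.asarray(candidates))
        if balance_weight_sum:
            trig = (
                case_rows["subject_id"].to_numpy()
                if design.case_fraction < 1.0
                else None
            )
            p_new = km_inclusion_probabilities(cohort, design, [chosen], trig)[0]
            w_new = 1.0 / p_new
            if abs(total + w_new - target) >= abs(total - target):
                continue
            total += w_new
        in_sample.add(chosen)
        new_rows.append(
            {
                "subject_id": chosen,
                "role": CONTROL,
                "matched_set_id": set_id,
                "sampling_time": case_row["sampling_time"],
            }
        )
    if not new_rows:
        return sample
    out = pd.concat([rec, pd.DataFrame(new_rows)], ignore_index=True)
    return replace(sample, records=out)


def validate_sample(sample: NCCSample, cohort: pd.DataFrame) -> None:
    """Assert the structural invariants of an NCC sample.

    Every matched set has exactly one case; every control was at risk
    (``time >= sampling_time``) and matching-compatible at its set's case
    event time; after deduplication each subject appears once.  Raises
    ``ValueError`` on the first violation.
    """
    rec = sample.records
    cohort_idx = cohort.set_index("subject_id")

    per_set = rec.groupby("matched_set_id")
    n_cases_per_set = per_set["role"].apply(lambda r: (r == CASE).sum())
    if (n_cases_per_set != 1).any():
        bad = n_cases_per_set[n_cases_per_set != 1].index.tolist()
        raise ValueError(f"matched sets without exactly one case: {bad}")

    if sample.deduplicated and rec["subject_id"].duplicated().any():
        dup = rec.loc[rec["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicated subjects after deduplication: {dup}")

    controls = rec[rec["role"] == CONTROL]
    ctrl_info = cohort_idx.loc[controls["subject_id"]]
    if (ctrl_info["time"].to_numpy() < controls["sampling_time"].to_numpy()).any():
        raise ValueError("control not at risk at its case's event time")
    if sample.matching_vars:
        case_rows = rec[rec["role"] == CASE].set_index("matched_set_id")
        for var in sample.matching_vars:
            case_level = cohort_idx.loc[
                case_rows.loc[controls["matched_set_id"], "subject_id"], var
            ].to_numpy()
            ctrl_level = ctrl_info[var].to_numpy()
            if (case_level != ctrl_level).any():
                raise ValueError(f"matching violated on {var!r}")


def write_sample(sample: NCCSample, path, sep: str = ",") -> None:
    sample.records.to_csv(path, sep=sep, index=False)


def read_sample(path, sep: str = ",", deduplicated: bool = True, m: int = 1,
                matching_vars=()) -> NCCSample:
    records = pd.read_csv(path, sep=sep)
    required = {"subject_id", "role", "matched_set_id"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"sample file missing columns: {sorted(missing)}")
    return NCCSample(
        records,
        deduplicated=deduplicated,
        m=m,
        matching_vars=list(matching_vars),
    )
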