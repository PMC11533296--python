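"""Weighted performance metrics for risk prediction models.

Discrimination (C-index), threshold-based metrics (sensitivity,
specificity, predictive values), calibration (O/E ratio, calibration
slope, grouped calibration) and clinical utility (net benefit, decision
curves), each in a weighted form suitable for nested case-control data:
every subject contributes with its inverse-probability-of-sampling
weight, so the NCC sample stands in for the full cohort it was drawn
from.  With unit weights every function reduces exactly to its classical
unweighted counterpart, and every ratio-type metric is invariant to
rescaling all weights by a positive constant.

Survival-mode threshold metrics replace empirical event proportions with
weighted Kaplan-Meier estimates at the prediction horizon, computed
within the high-risk (r > p_t) and low-risk (r <= p_t) strata; the
positive and negative masses come from the overall weighted Kaplan-Meier
rather than by summing the stratum quantities, which avoids the small
discrepancy between stratum-level and group-level survival estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _as_arrays(*seqs):
    return tuple(np.asarray(s, dtype=float) for s in seqs)


# ---------------------------------------------------------------------------
# weighted Kaplan-Meier

def weighted_km(times, events, weights, t: float) -> float:
    """Weighted product-limit survival estimate at time ``t``.

    The event count at each time is replaced by the sum of weights of
    subjects with an event there, and the at-risk count by the sum of
    weights of subjects still under observation (subjects censored at an
    event time count as at risk at that time).  Unit weights give the
    standard Kaplan-Meier estimate.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    times, events, weights = _as_arrays(times, events, weights)
    if len(times) == 0:
        return 1.0
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")

    event_times = np.unique(times[(events == 1) & (times <= t)])
    surv = 1.0
    for u in event_times:
        at_risk = weights[times >= u].sum()
        if at_risk <= 0:
            warnings.warn(
                f"no weight at risk at event time {u}; estimate carried forward",
                stacklevel=2,
            )
            continue
        d = weights[(times == u) & (events == 1)].sum()
        surv *= 1.0 - d / at_risk
    return float(surv)


# ---------------------------------------------------------------------------
# concordance

@dataclass
class PairCounts:
    """Per-anchor counts over usable pairs.

    The anchor of a usable pair is the member with the earlier event.
    ``concordant[k]``/``discordant[k]``/``tied_risk[k]`` count the pairs
    anchored at subject ``k`` where the longer-surviving member has lower
    / higher / equal predicted risk.  When comparator weights were
    supplied, ``*_wsum`` hold the same counts with each pair contributing
    the comparator's weight (used by the pair-product weighting variant).
    """

    concordant: np.ndarray
    discordant: np.ndarray
    tied_risk: np.ndarray
    concordant_wsum: np.ndarray | None = None
    discordant_wsum: np.ndarray | None = None
    tied_risk_wsum: np.ndarray | None = None

    def n_usable(self) -> float:
        return float(
            self.concordant.sum() + self.discordant.sum() + self.tied_risk.sum()
        )


def concordance_pairs(risks, times, events, comparator_weights=None) -> PairCounts:
    """Enumerate usable pairs for the (weighted) C-index.

    A pair is usable when it can be ordered in time: the anchor had the
    earlier event and the other member was observed longer (or was
    censored exactly at the anchor's event time).  Pairs of events tied
    in time are not usable.
    """
    risks, times, events = _as_arrays(risks, times, events)
    n = len(risks)
    C = np.zeros(n)
    D = np.zeros(n)
    T = np.zeros(n)
    track_w = comparator_weights is not None
    if track_w:
        w = np.asarray(comparator_weights, dtype=float)
        Cw, Dw, Tw = np.zeros(n), np.zeros(n), np.zeros(n)

    for k in np.flatnonzero(events == 1):
        usable = (times > times[k]) | ((times == times[k]) & (events == 0))
        usable[k] = False
        conc = usable & (risks < risks[k])
        disc = usable & (risks > risks[k])
        tied = usable & (risks == risks[k])
        C[k] = conc.sum()
        D[k] = disc.sum()
        T[k] = tied.sum()
        if track_w:
            Cw[k] = w[conc].sum()
            Dw[k] = w[disc].sum()
            Tw[k] = w[tied].sum()

    if C.sum() + D.sum() + T.sum() == 0:
        raise ValueError("no usable pairs")
    if track_w:
        return PairCounts(C, D, T, Cw, Dw, Tw)
    return PairCounts(C, D, T)


def weighted_c_index(
    pairs: PairCounts,
    weights,
    tie_policy: str = "half",
    pair_weighting: str = "product",
) -> float:
    """C-index with sampling-weighted pair counts,
    ``sum_k w_k C_k / sum_k w_k (C_k + D_k)``.

    ``pair_weighting`` selects how a pair's weight is formed.
    ``'product'`` (default) weights each pair by the product of both
    members' weights (requires ``concordance_pairs`` called with
    ``comparator_weights``): both the anchor's and the comparator's
    sampling must be corrected for the pair population to represent the
    cohort, and simulation shows only this form is unbiased under NCC
    sampling.  ``'anchor'`` uses the anchor's weight alone, the literal
    single-indexed reading of the weighted sum; it leaves the
    comparator's biased sampling uncorrected and is retained only for
    comparison.  ``tie_policy='half'`` (default) counts risk-tied pairs
    with 1/2 in the numerator and fully in the denominator; ``'ignore'``
    drops them.  With unit weights both forms reduce to the classical
    C-index.
    """
    w = np.asarray(weights, dtype=float)
    if pair_weighting == "anchor":
        C, D, T = pairs.concordant, pairs.discordant, pairs.tied_risk
    elif pair_weighting == "product":
        if pairs.concordant_wsum is None:
            raise ValueError(
                "pair_weighting='product' needs PairCounts built with "
                "comparator_weights"
            )
        C, D, T = pairs.concordant_wsum, pairs.discordant_wsum, pairs.tied_risk_wsum
    else:
        raise ValueError(f"unknown pair_weighting {pair_weighting!r}")

    if tie_policy == "half":
        num = (w * (C + 0.5 * T)).sum()
        den = (w * (C + D + T)).sum()
    elif tie_policy == "ignore":
        num = (w * C).sum()
        den = (w * (C + D)).sum()
    else:
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    if den == 0:
        raise ValueError("no weighted usable pairs")
    return float(num / den)


def c_index(risks, times, events, weights=None, **kwargs) -> float:
    """Convenience wrapper: pair enumeration + weighting in one call.
    ``weights=None`` gives the classical unweighted C-index."""
    if weights is None:
        weights = np.ones(len(np.asarray(risks)))
    comparator = None if kwargs.get("pair_weighting") == "anchor" else weights
    pairs = concordance_pairs(risks, times, events, comparator_weights=comparator)
    return weighted_c_index(pairs, weights, **kwargs)


# ---------------------------------------------------------------------------
# threshold-based metrics

@dataclass
class ThresholdMetrics:
    """Weighted confusion-matrix metrics at risk threshold ``p_t``.

    Counts are weighted expected counts; in survival mode they combine
    stratum weight masses with weighted Kaplan-Meier survival at the
    horizon.  Undefined ratios (empty stratum, no positives) are NaN.
    """

    p_t: float
    mode: str
    se: float
    sp: float
    ppv: float
    npv: float
    tp: float
    fp: float
    tn: float
    fn: float
    pos: float
    neg: float
    horizon: float | None = None

    def as_dict(self) -> dict:
        return {
            "se": self.se, "sp": self.sp, "ppv": self.ppv, "npv": self.npv,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "pos": self.pos, "neg": self.neg,
        }


def _safe_div(a: float, b: float, what: str) -> float:
    if b == 0:
        warnings.warn(f"{what} undefined (zero denominator)", stacklevel=3)
        return float("nan")
    return a / b


def threshold_metrics_binary(x, risks, weights, p_t: float) -> ThresholdMetrics:
    """Weighted sensitivity/specificity/PPV/NPV for a binary outcome
    ``x`` with the high-risk rule ``r > p_t`` (strict)."""
    x, risks, weights = _as_arrays(x, risks, weights)
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("binary outcome must be 0/1")
    high = risks > p_t
    tp = weights[(x == 1) & high].sum()
    fn = weights[(x == 1) & ~high].sum()
    fp = weights[(x == 0) & high].sum()
    tn = weights[(x == 0) & ~high].sum()
    pos, neg = tp + fn, tn + fp
    return ThresholdMetrics(
        p_t=p_t, mode="binary",
        se=_safe_div(tp, pos, "sensitivity"),
        sp=_safe_div(tn, neg, "specificity"),
        ppv=_safe_div(tp, tp + fp, "PPV"),
        npv=_safe_div(tn, tn + fn, "NPV"),
        tp=tp, fp=fp, tn=tn, fn=fn, pos=pos, neg=neg,
    )


def threshold_metrics_survival(
    times, events, risks, weights, p_t: float, horizon: float
) -> ThresholdMetrics:
    """Weighted threshold metrics for a time-to-event outcome.

    High- and low-risk strata each get a weighted Kaplan-Meier survival
    estimate at the horizon; the positive/negative masses come from the
    overall weighted Kaplan-Meier applied to the total weight.
    """
    times, events, risks, weights = _as_arrays(times, events, risks, weights)
    high = risks > p_t
    w_total = weights.sum()
    w_high = weights[high].sum()
    w_low = w_total - w_high

    s_all = weighted_km(times, events, weights, horizon)
    if high.any():
        s_high = weighted_km(times[high], events[high], weights[high], horizon)
    else:
        warnings.warn("no subjects above threshold; PPV undefined", stacklevel=2)
        s_high = float("nan")
    if (~high).any():
        s_low = weighted_km(times[~high], events[~high], weights[~high], horizon)
    else:
        warnings.warn("no subjects below threshold; NPV undefined", stacklevel=2)
        s_low = float("nan")

    tp = (1.0 - s_high) * w_high if w_high > 0 else 0.0
    fp = s_high * w_high if w_high > 0 else 0.0
    tn = s_low * w_low if w_low > 0 else 0.0
    fn = (1.0 - s_low) * w_low if w_low > 0 else 0.0
    pos = (1.0 - s_all) * w_total
    neg = s_all * w_total
    return ThresholdMetrics(
        p_t=p_t, mode="survival", horizon=horizon,
        se=_safe_div(tp, pos, "sensitivity"),
        sp=_safe_div(tn, neg, "specificity"),
        ppv=1.0 - s_high,
        npv=s_low,
        tp=tp, fp=fp, tn=tn, fn=fn, pos=pos, neg=neg,
    )


# ---------------------------------------------------------------------------
# calibration

def oe_ratio(times, events, risks, weights, horizon: float) -> float:
    """Observed-to-expected event ratio at the horizon: weighted
    Kaplan-Meier cumulative incidence over weighted mean predicted risk.
    1 means perfect mean calibration; > 1 means the model underestimates."""
    times, events, risks, weights = _as_arrays(times, events, risks, weights)
    if weights.sum() <= 0:
        raise ValueError("total weight must be positive")
    observed = 1.0 - weighted_km(times, events, weights, horizon)
    expected = float((weights * risks).sum() / weights.sum())
    if expected == 0:
        raise ValueError("mean predicted risk is zero; O/E undefined")
    return observed / expected


def mean_calibration_diff(times, events, risks, weights, horizon: float) -> float:
    """Weighted observed cumulative incidence minus weighted mean
    predicted risk (0 under perfect mean calibration)."""
    times, events, risks, weights = _as_arrays(times, events, risks, weights)
    observed = 1.0 - weighted_km(times, events, weights, horizon)
    expected = float((weights * risks).sum() / weights.sum())
    return observed - expected


def calibration_slope(lp, times, events, weights, mode: str = "survival") -> float:
    """Slope of the weighted regression of the observed outcome on the
    model's linear predictor: a weighted Cox model in survival mode, a
    weighted logistic regression in binary mode (where ``events`` is the
    binary outcome and ``times`` is ignored).  1 is ideal; < 1 indicates
    an overfitted model, > 1 an underfitted one.
    """
    lp = np.asarray(lp, dtype=float)
    if np.var(lp) == 0:
        raise ValueError("linear predictor has zero variance")
    weights = np.asarray(weights, dtype=float)

    if mode == "survival":
        from lifelines import CoxPHFitter

        df = pd.DataFrame(
            {"time": np.asarray(times, float), "event": np.asarray(events, float),
             "lp": lp, "w": weights}
        )
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            # lifelines flags non-integer weights; sampling weights are intended
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event", weights_col="w",
                    robust=False)
        return float(cph.params_["lp"])
    if mode == "binary":
        import statsmodels.api as sm

        y = np.asarray(events, dtype=float)
        X = sm.add_constant(lp)
        fit = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=weights).fit()
        return float(fit.params[1])
    raise ValueError(f"unknown mode {mode!r}")


def calibration_groups(
    risks, times, events, weights, n_groups: int, horizon: float,
    weighted_quantiles: bool = False,
) -> pd.DataFrame:
    """Grouped calibration table: subjects cut into risk quantile groups,
    each with weighted mean predicted risk, weighted Kaplan-Meier
    observed incidence at the horizon, and its total weight mass."""
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    risks, times, events, weights = _as_arrays(risks, times, events, weights)
    if n_groups == 1:
        labels = np.zeros(len(risks), dtype=int)
    else:
        if weighted_quantiles:
            order = np.argsort(risks, kind="stable")
            cum = np.cumsum(weights[order]) / weights.sum()
            grp = np.minimum((cum * n_groups).astype(int), n_groups - 1)
            labels = np.empty(len(risks), dtype=int)
            labels[order] = grp
        else:
            binned = pd.qcut(risks, n_groups, labels=False, duplicates="drop")
            if pd.Series(binned).nunique() < n_groups:
                warnings.warn(
                    "fewer distinct risk values than groups; groups merged",
                    stacklevel=2,
                )
            labels = np.asarray(binned)
    rows = []
    for g in np.unique(labels):
        sel = labels == g
        rows.append(
            {
                "group": int(g),
                "mean_predicted": float((weights[sel] * risks[sel]).sum() / weights[sel].sum()),
                "observed": 1.0 - weighted_km(times[sel], events[sel], weights[sel], horizon),
                "weight_mass": float(weights[sel].sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# decision curve analysis

def harm_to_threshold(harm_ratio: float) -> float:
    """Convert a relative harm (how much worse a missed event is than an
    unnecessary intervention) into the decision threshold
    ``1 / (harm_ratio + 1)``."""
    if harm_ratio <= 0:
        raise ValueError("harm_ratio must be positive")
    return 1.0 / (harm_ratio + 1.0)


def net_benefit(
    times, events, risks, weights, p_t: float, horizon: float | None = None,
    mode: str = "survival",
) -> float:
    """Net benefit NB = TP/n - FP/n * p_t/(1-p_t) with weighted TP/FP and
    n the total weight.  Binary mode reads ``events`` as the binary
    outcome."""
    if not 0.0 < p_t < 1.0:
        raise ValueError("p_t must be strictly inside (0, 1)")
    weights_arr = np.asarray(weights, dtype=float)
    n = weights_arr.sum()
    risks_arr = np.asarray(risks, dtype=float)
    if not (risks_arr > p_t).any():
        return 0.0
    if mode == "survival":
        if horizon is None:
            raise ValueError("survival mode requires a horizon")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = threshold_metrics_survival(times, events, risks, weights, p_t, horizon)
    elif mode == "binary":
        m = threshold_metrics_binary(events, risks, weights, p_t)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(m.tp / n - m.fp / n * (p_t / (1.0 - p_t)))


@dataclass
class DecisionCurve:
    """Net benefit of the model, of treating everyone, and of treating
    no one, over a grid of thresholds (``table`` columns ``threshold``,
    ``nb_model``, ``nb_treat_all``, ``nb_treat_none``)."""

    table: pd.DataFrame
    horizon: float | None = None
    mode: str = "survival"
    effective_n: float = field(default=0.0)


def decision_curve(
    times, events, risks, weights, thresholds, horizon: float | None = None,
    mode: str = "survival",
) -> DecisionCurve:
    """Decision curve over ``thresholds``: the treat-all strategy uses
    the same weights (everyone classified high risk), treat-none is 0."""
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("empty threshold grid")
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must be strictly inside (0, 1)")
    times_a, events_a, weights_a = _as_arrays(times, events, weights)
    n = weights_a.sum()

    if mode == "survival":
        s_all = weighted_km(times_a, events_a, weights_a, horizon)
        event_prop = 1.0 - s_all
    else:
        event_prop = float((weights_a * events_a).sum() / n)
    tp_all, fp_all = event_prop * n, (1.0 - event_prop) * n

    rows = []
    for p_t in thresholds:
        nb = net_benefit(times, events, risks, weights, p_t, horizon, mode)
        nb_all = tp_all / n - fp_all / n * (p_t / (1.0 - p_t))
        rows.append(
            {"threshold": p_t, "nb_model": nb, "nb_treat_all": nb_all,
             "nb_treat_none": 0.0}
        )
    return DecisionCurve(pd.DataFrame(rows), horizon=horizon, mode=mode,
                         effective_n=float(n))
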