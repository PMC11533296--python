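import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nccvalidate import (
    CensoringSpec,
    CohortConfig,
    c_index,
    calibration_groups,
    calibration_slope,
    concordance_pairs,
    decision_curve,
    harm_to_threshold,
    net_benefit,
    oe_ratio,
    simulate_cohort,
    threshold_metrics_binary,
    threshold_metrics_survival,
    weighted_c_index,
    weighted_km,
)


class TestWeightedKM:
    def test_unit_weights_match_lifelines(self, survival_data):
        from lifelines import KaplanMeierFitter

        d = survival_data
        kmf = KaplanMeierFitter().fit(d["times"], d["events"])
        for t in [0.5, 2.0, 5.0, 10.0]:
            ref = float(kmf.predict(t))
            got = weighted_km(d["times"], d["events"], np.ones(len(d["times"])), t)
            assert got == pytest.approx(ref, abs=1e-12)

    def test_all_events_after_t_gives_one(self):
        assert weighted_km([5.0, 6.0], [1, 1], [1.0, 2.0], 3.0) == 1.0

    def test_hand_product_limit_step(self):
        # event at t=1 (w=1), censored at t=2 (w=3): at-risk mass 4
        assert weighted_km([1.0, 2.0], [1, 0], [1.0, 3.0], 1.5) == pytest.approx(0.75)

    def test_non_increasing_in_t(self, survival_data):
        d = survival_data
        grid = np.linspace(0, d["times"].max(), 25)
        values = [weighted_km(d["times"], d["events"], d["weights"], t) for t in grid]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))
        assert values[0] == 1.0


class TestConcordance:
    # case (t=1, r=0.2), case (t=2, r=0.5), control (censored t=5, r=0.3)
    times = [1.0, 2.0, 5.0]
    events = [1, 1, 0]
    risks = [0.2, 0.5, 0.3]

    def test_exhaustive_pair_enumeration(self):
        pairs = concordance_pairs(self.risks, self.times, self.events)
        assert pairs.discordant.tolist() == [2.0, 0.0, 0.0]
        assert pairs.concordant.tolist() == [0.0, 1.0, 0.0]
        assert pairs.n_usable() == 3

    def test_all_tied_risks(self):
        pairs = concordance_pairs([0.4, 0.4, 0.4], self.times, self.events)
        assert pairs.concordant.sum() == 0
        assert pairs.discordant.sum() == 0
        assert pairs.tied_risk.sum() == 3

    def test_perfect_ordering_has_no_discordance(self):
        pairs = concordance_pairs([0.9, 0.5, 0.1], self.times, self.events)
        assert pairs.discordant.sum() == 0

    def test_no_usable_pairs_rejected(self):
        with pytest.raises(ValueError, match="usable"):
            concordance_pairs([0.1], [1.0], [1])

    def test_anchor_weighted_worked_example(self):
        pairs = concordance_pairs(self.risks, self.times, self.events)
        value = weighted_c_index(pairs, [1.0, 2.0, 1.0], pair_weighting="anchor")
        assert value == pytest.approx((2 * 1) / (1 * 2 + 2 * 1))

    def test_unit_weights_reduce_to_unweighted(self, survival_data):
        d = survival_data
        unit = np.ones(len(d["risks"]))
        pairs = concordance_pairs(d["risks"], d["times"], d["events"],
                                  comparator_weights=unit)
        unweighted = pairs.concordant.sum() / (
            pairs.concordant.sum() + pairs.discordant.sum()
        )
        got = weighted_c_index(pairs, unit)
        assert got == pytest.approx(unweighted, abs=1e-12)

    def test_unit_weights_match_lifelines(self, survival_data):
        from lifelines.utils import concordance_index

        d = survival_data
        # lifelines orders by predicted survival time: use -risk
        ref = concordance_index(d["times"], -d["risks"], d["events"])
        got = c_index(d["risks"], d["times"], d["events"])
        assert got == pytest.approx(ref, abs=1e-12)

    def test_unit_weights_match_sksurv(self, survival_data):
        from sksurv.metrics import concordance_index_censored

        d = survival_data
        ref = concordance_index_censored(
            d["events"].astype(bool), d["times"], d["risks"]
        )[0]
        got = c_index(d["risks"], d["times"], d["events"])
        assert got == pytest.approx(ref, abs=1e-12)

    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_weight_rescaling(self, scale):
        w = np.array([1.0, 2.0, 3.0])
        for pw in ("anchor", "product"):
            assert c_index(
                self.risks, self.times, self.events, w, pair_weighting=pw
            ) == pytest.approx(
                c_index(self.risks, self.times, self.events, scale * w,
                        pair_weighting=pw)
            )

    def test_product_pair_weighting_close_to_anchor_on_unit_weights(self, survival_data):
        d = survival_data
        unit = np.ones(len(d["risks"]))
        pairs = concordance_pairs(d["risks"], d["times"], d["events"],
                                  comparator_weights=unit)
        anchor = weighted_c_index(pairs, unit, pair_weighting="anchor")
        product = weighted_c_index(pairs, unit, pair_weighting="product")
        assert product == pytest.approx(anchor, abs=1e-12)


class TestThresholdMetricsBinary:
    def test_worked_confusion_matrix(self):
        """2 cases (w=1) above threshold, 2 controls (w=10) with one
        above: SE=1, SP=0.5, PPV=2/12, NPV=1."""
        x = [1, 1, 0, 0]
        risks = [0.6, 0.7, 0.6, 0.1]
        w = [1.0, 1.0, 10.0, 10.0]
        m = threshold_metrics_binary(x, risks, w, p_t=0.5)
        assert (m.tp, m.fn, m.fp, m.tn) == (2.0, 0.0, 10.0, 10.0)
        assert m.se == 1.0
        assert m.sp == 0.5
        assert m.ppv == pytest.approx(2 / 12)
        assert m.npv == 1.0
        assert m.pos + m.neg == pytest.approx(np.sum(w))

    def test_unit_weights_match_sklearn_confusion_matrix(self, survival_data):
        from sklearn.metrics import confusion_matrix

        d = survival_data
        x = d["events"]
        pred = (d["risks"] > 0.3).astype(int)
        tn, fp, fn, tp = confusion_matrix(x, pred).ravel()
        m = threshold_metrics_binary(x, d["risks"], np.ones(len(x)), 0.3)
        assert m.se == pytest.approx(tp / (tp + fn), abs=1e-12)
        assert m.sp == pytest.approx(tn / (tn + fp), abs=1e-12)
        assert m.ppv == pytest.approx(tp / (tp + fp), abs=1e-12)
        assert m.npv == pytest.approx(tn / (tn + fn), abs=1e-12)

    def test_common_case_weight_cancels_in_sensitivity(self, survival_data):
        """Typical NCC: all cases share one weight, so weighted SE equals
        the unweighted SE exactly (the case weight cancels in TP/Pos)."""
        d = survival_data
        x = d["events"]
        w = np.where(x == 1, 3.7, d["weights"])  # common case weight
        weighted = threshold_metrics_binary(x, d["risks"], w, 0.3)
        unweighted = threshold_metrics_binary(x, d["risks"], np.ones(len(x)), 0.3)
        assert weighted.se == pytest.approx(unweighted.se, abs=1e-12)

    def test_degenerate_strata_warn_and_return_nan(self):
        with pytest.warns(UserWarning):
            m = threshold_metrics_binary([1, 1], [0.9, 0.8], [1, 1], 0.5)
        assert np.isnan(m.sp)


class TestThresholdMetricsSurvival:
    def test_reduces_to_binary_without_censoring(self):
        rng = np.random.default_rng(2)
        n = 80
        times = rng.uniform(1, 20, n)
        events = np.ones(n, dtype=int)
        risks = rng.uniform(0, 1, n)
        w = rng.uniform(0.5, 3.0, n)
        horizon = 10.0
        x = (times <= horizon).astype(int)
        surv = threshold_metrics_survival(times, events, risks, w, 0.4, horizon)
        binary = threshold_metrics_binary(x, risks, w, 0.4)
        for name in ("se", "sp", "ppv", "npv"):
            assert getattr(surv, name) == pytest.approx(
                getattr(binary, name), abs=1e-12
            ), name

    def test_everyone_below_threshold(self, survival_data):
        d = survival_data
        with pytest.warns(UserWarning, match="above threshold"):
            m = threshold_metrics_survival(
                d["times"], d["events"], d["risks"], d["weights"], 0.99, 5.0
            )
        assert m.se == 0.0
        assert m.sp == 1.0


class TestOERatio:
    def test_perfect_mean_calibration(self):
        # 1 event among 4, no censoring by horizon, risks equal event rate
        times = [0.5, 2.0, 2.0, 2.0]
        events = [1, 0, 0, 0]
        risks = [0.25] * 4
        w = np.ones(4)
        assert oe_ratio(times, events, risks, w, 1.0) == pytest.approx(1.0)

    def test_halving_risks_doubles_ratio(self, survival_data):
        d = survival_data
        base = oe_ratio(d["times"], d["events"], d["risks"], d["weights"], 5.0)
        halved = oe_ratio(d["times"], d["events"], 0.5 * d["risks"], d["weights"], 5.0)
        assert halved == pytest.approx(2 * base)

    def test_known_miscalibration_recovered(self):
        """A model whose risks are half the truth shows O/E ~ 2.

        Censoring is kept covariate-independent here so that the
        marginal Kaplan-Meier incidence is an unbiased estimate of the
        mean true risk and the factor-2 oracle is exact.
        """
        config = CohortConfig(
            n_subjects=20_000,
            risk_multiplier=0.5,
            censoring=CensoringSpec(rate=0.05),
            seed=21,
        )
        cohort = simulate_cohort(config)
        got = oe_ratio(
            cohort["time"], cohort["event"], cohort["risk"],
            np.ones(len(cohort)), config.horizon,
        )
        assert got == pytest.approx(2.0, abs=0.25)


class TestCalibrationSlope:
    def test_recovers_unity_on_correctly_specified_model(self):
        config = CohortConfig(n_subjects=5000, seed=31)
        cohort = simulate_cohort(config)
        slope = calibration_slope(
            cohort["lp"], cohort["time"], cohort["event"], np.ones(len(cohort))
        )
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_doubling_lp_halves_slope(self):
        config = CohortConfig(n_subjects=5000, seed=32)
        cohort = simulate_cohort(config)
        unit = np.ones(len(cohort))
        base = calibration_slope(cohort["lp"], cohort["time"], cohort["event"], unit)
        doubled = calibration_slope(
            2.0 * cohort["lp"], cohort["time"], cohort["event"], unit
        )
        assert doubled == pytest.approx(base / 2, rel=1e-6)

    def test_survival_mode_matches_statsmodels_phreg(self, survival_data):
        from statsmodels.duration.hazard_regression import PHReg

        d = survival_data
        lp = np.log(d["risks"])
        got = calibration_slope(lp, d["times"], d["events"], np.ones(len(lp)))
        ref = PHReg(d["times"], lp.reshape(-1, 1), status=d["events"]).fit()
        assert got == pytest.approx(float(ref.params[0]), abs=1e-4)

    def test_binary_mode_matches_sklearn(self, survival_data):
        from sklearn.linear_model import LogisticRegression

        d = survival_data
        lp = np.log(d["risks"])
        y = d["events"]
        got = calibration_slope(lp, None, y, np.ones(len(lp)), mode="binary")
        ref = LogisticRegression(C=1e10, tol=1e-10).fit(lp.reshape(-1, 1), y)
        assert got == pytest.approx(float(ref.coef_[0][0]), abs=1e-4)

    def test_constant_lp_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            calibration_slope([1.0, 1.0], [1.0, 2.0], [1, 0], [1.0, 1.0])


class TestCalibrationGroups:
    def test_single_group_matches_oe_ingredients(self, survival_data):
        d = survival_data
        table = calibration_groups(
            d["risks"], d["times"], d["events"], d["weights"], 1, 5.0
        )
        w = d["weights"]
        assert table["mean_predicted"].iloc[0] == pytest.approx(
            (w * d["risks"]).sum() / w.sum()
        )
        assert table["observed"].iloc[0] == pytest.approx(
            1 - weighted_km(d["times"], d["events"], w, 5.0)
        )
        assert table["weight_mass"].iloc[0] == pytest.approx(w.sum())

    def test_groups_partition_weight_mass(self, survival_data):
        d = survival_data
        table = calibration_groups(
            d["risks"], d["times"], d["events"], d["weights"], 5, 5.0
        )
        assert len(table) == 5
        assert table["weight_mass"].sum() == pytest.approx(d["weights"].sum())

    def test_calibrated_simulation_tracks_diagonal(self):
        config = CohortConfig(n_subjects=8000, seed=33)
        cohort = simulate_cohort(config)
        table = calibration_groups(
            cohort["risk"], cohort["time"], cohort["event"],
            np.ones(len(cohort)), 5, config.horizon,
        )
        assert np.allclose(table["observed"], table["mean_predicted"], atol=0.02)

    def test_few_distinct_risks_merges_with_warning(self):
        with pytest.warns(UserWarning, match="merged"):
            calibration_groups(
                [0.1] * 4 + [0.9] * 4,
                np.arange(1.0, 9.0),
                [1, 0, 1, 0, 1, 0, 1, 0],
                np.ones(8),
                5,
                10.0,
            )


class TestDecisionCurve:
    @pytest.mark.parametrize("harm, expected", [(4.0, 0.2), (1.0, 0.5), (9.0, 0.1)])
    def test_harm_to_threshold(self, harm, expected):
        assert harm_to_threshold(harm) == pytest.approx(expected)

    def test_nonpositive_harm_rejected(self):
        with pytest.raises(ValueError):
            harm_to_threshold(0.0)

    def test_nobody_above_threshold_gives_zero(self, survival_data):
        d = survival_data
        nb = net_benefit(d["times"], d["events"], d["risks"], d["weights"],
                         0.95, 5.0)
        assert nb == 0.0

    def test_treat_all_crosses_zero_at_event_proportion(self, survival_data):
        d = survival_data
        pi = 1 - weighted_km(d["times"], d["events"], d["weights"], 5.0)
        curve = decision_curve(
            d["times"], d["events"], np.ones(len(d["risks"])), d["weights"],
            [pi], horizon=5.0,
        )
        assert curve.table["nb_treat_all"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_model_identical_to_treat_all_when_all_risks_one(self, survival_data):
        d = survival_data
        ones = np.ones(len(d["risks"]))
        curve = decision_curve(
            d["times"], d["events"], ones, d["weights"],
            [0.05, 0.2, 0.5], horizon=5.0,
        )
        assert np.allclose(curve.table["nb_model"], curve.table["nb_treat_all"])
        assert np.all(curve.table["nb_treat_none"] == 0.0)

    def test_informative_model_beats_treat_all_above_prevalence(self):
        config = CohortConfig(n_subjects=8000, seed=35)
        cohort = simulate_cohort(config)
        unit = np.ones(len(cohort))
        pi = 1 - weighted_km(cohort["time"], cohort["event"], unit, config.horizon)
        curve = decision_curve(
            cohort["time"], cohort["event"], cohort["risk"], unit,
            np.linspace(pi + 0.01, pi + 0.04, 4), horizon=config.horizon,
        )
        assert (curve.table["nb_model"] >= curve.table["nb_treat_all"] - 1e-9).all()

    def test_invalid_threshold_rejected(self, survival_data):
        d = survival_data
        with pytest.raises(ValueError):
            net_benefit(d["times"], d["events"], d["risks"], d["weights"], 1.0, 5.0)
        with pytest.raises(ValueError, match="empty"):
            decision_curve(d["times"], d["events"], d["risks"], d["weights"],
                           [], horizon=5.0)


class TestWeightScaleInvariance:
    """Ratio-type weighted metrics are unchanged when every weight is
    multiplied by the same positive constant."""

    @pytest.mark.parametrize("scale", [0.1, 3.0, 250.0])
    def test_all_ratio_metrics(self, survival_data, scale):
        d = survival_data
        w, ws = d["weights"], scale * d["weights"]
        assert weighted_km(d["times"], d["events"], w, 5.0) == pytest.approx(
            weighted_km(d["times"], d["events"], ws, 5.0), abs=1e-12
        )
        assert oe_ratio(d["times"], d["events"], d["risks"], w, 5.0) == pytest.approx(
            oe_ratio(d["times"], d["events"], d["risks"], ws, 5.0)
        )
        m1 = threshold_metrics_survival(d["times"], d["events"], d["risks"], w, 0.3, 5.0)
        m2 = threshold_metrics_survival(d["times"], d["events"], d["risks"], ws, 0.3, 5.0)
        for name in ("se", "sp", "ppv", "npv"):
            assert getattr(m1, name) == pytest.approx(getattr(m2, name), abs=1e-12)
        assert net_benefit(
            d["times"], d["events"], d["risks"], w, 0.1, 5.0
        ) == pytest.approx(net_benefit(d["times"], d["events"], d["risks"], ws, 0.1, 5.0))
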