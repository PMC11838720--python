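"""Validation: coverage proportions, chi-squared comparison, quantile regression."""

import numpy as np
import pandas as pd
import pytest

from deltacheck import (CohortConfig, chisq_compare, compute_deltas,
                        cross_validate, estimate_dcls, generate_cohort,
                        proportion_outside, quantreg_group_test,
                        split_dev_val)
from deltacheck.estimation import DclEstimate
from deltacheck.validation import (ValidationReport, pinball_loss,
                                   pinball_quantile)
from deltacheck.reference import DEFAULT_ANALYTES


def _dcl(limit, metric="absDPC", group="O", analyte="cortisol"):
    return DclEstimate(analyte=analyte, group=group, metric=metric,
                       percentile=95.0, limit=limit, n_dev=1000)


class TestProportionOutside:
    def test_bounding_limit_gives_zero(self, cortisol_deltas):
        val = cortisol_deltas[cortisol_deltas["group"] == "O"]
        r = proportion_outside(val, _dcl(val["abs_dpc"].max()))
        assert r.n_outside == 0
        assert r.proportion_outside == 0.0

    def test_zero_limit_gives_everything(self, cortisol_deltas):
        val = cortisol_deltas[cortisol_deltas["group"] == "O"]
        val = val[val["abs_dpc"] > 0]
        r = proportion_outside(val, _dcl(0.0))
        assert r.proportion_outside == 100.0

    def test_strict_vs_inclusive_at_limit(self):
        df = compute_deltas(pd.DataFrame({
            "analyte": "cortisol", "group": "O", "sex": "F",
            "prev_value": [100.0, 100.0], "curr_value": [110.0, 120.0],
        }))
        at_limit = _dcl(10.0)
        assert proportion_outside(df, at_limit, strict=True).n_outside == 1
        assert proportion_outside(df, at_limit, strict=False).n_outside == 2

    def test_monotone_in_limit(self, cortisol_deltas):
        val = cortisol_deltas[cortisol_deltas["group"] == "O"]
        counts = [proportion_outside(val, _dcl(l)).n_outside
                  for l in np.linspace(0, 60, 20)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_empty_validation_set_rejected(self, cortisol_deltas):
        with pytest.raises(ValueError):
            proportion_outside(cortisol_deltas.iloc[0:0], _dcl(1.0))


class TestCrossValidate:
    def test_four_reports_and_consistency(self, cortisol_deltas):
        split = split_dev_val(cortisol_deltas, 0.6, seed=1)
        dev = cortisol_deltas.loc[split.dev_index()]
        val = cortisol_deltas.loc[split.val_index()]
        dcls = {d.group: d for d in estimate_dcls(dev)
                if d.metric == "absDPC"}
        val_ie = val[val["group"] == "IE"]
        val_o = val[val["group"] == "O"]
        reports = cross_validate(dcls, val_ie, val_o)
        assert {(r.dcl_source, r.applied_to) for r in reports} == {
            ("IE", "IE"), ("IE", "O"), ("O", "IE"), ("O", "O")
        }
        own = next(r for r in reports
                   if r.dcl_source == "O" and r.applied_to == "O")
        direct = proportion_outside(val_o, dcls["O"], applied_to="O")
        assert own.n_outside == direct.n_outside

    def test_exchangeable_groups_all_near_nominal(self):
        """Same generating process in both groups: all four own/cross

        proportions sit near 5%."""
        spec = DEFAULT_ANALYTES["cortisol"]
        cfg = CohortConfig(analytes=(spec,), n_pairs_ie=4000, n_pairs_o=4000,
                           seed=5)
        # force identical group distributions
        cfg = CohortConfig(
            analytes=(type(spec)(**{**spec.__dict__,
                                    "median_ie": spec.median_o,
                                    "iqr_ie": spec.iqr_o}),),
            n_pairs_ie=4000, n_pairs_o=4000, seed=5,
        )
        rec = compute_deltas(generate_cohort(cfg))
        split = split_dev_val(rec, 0.6, seed=2)
        dev, val = rec.loc[split.dev_index()], rec.loc[split.val_index()]
        dcls = {d.group: d for d in estimate_dcls(dev) if d.metric == "absDPC"}
        reports = cross_validate(dcls, val[val["group"] == "IE"],
                                 val[val["group"] == "O"])
        for r in reports:
            assert 3.0 < r.proportion_outside < 7.0

    def test_missing_group_reduces_reports(self, cortisol_deltas):
        split = split_dev_val(cortisol_deltas, 0.6, seed=1)
        dev = cortisol_deltas.loc[split.dev_index()]
        val = cortisol_deltas.loc[split.val_index()]
        dcls = {d.group: d for d in estimate_dcls(dev) if d.metric == "absDD"}
        reports = cross_validate(dcls, None, val[val["group"] == "O"])
        assert {(r.dcl_source, r.applied_to) for r in reports} == {
            ("IE", "O"), ("O", "O")
        }


class TestChisq:
    def _report(self, n_out, n_val, group):
        return ValidationReport(analyte="x", metric="absDD",
                                dcl_source="combined", applied_to=group,
                                limit=1.0, n_val=n_val, n_outside=n_out)

    def test_identical_proportions_statistic_zero(self):
        c = chisq_compare(self._report(50, 1000, "IE"),
                          self._report(50, 1000, "O"))
        assert c.statistic == pytest.approx(0.0)
        assert c.p_value == pytest.approx(1.0)

    def test_hand_computed_expected_counts(self):
        """Pearson statistic for [[10,90],[50,50]] equals sum (O-E)^2/E

        with margin-derived expectations E = [[30,70],[30,70]]."""
        c = chisq_compare(self._report(10, 100, "IE"),
                          self._report(50, 100, "O"))
        hand = (20**2 / 30 + 20**2 / 70) * 2  # 38.0952...
        assert c.statistic == pytest.approx(hand, abs=5e-3)
        assert c.p_value < 1e-9

    def test_label_swap_invariance(self):
        a = chisq_compare(self._report(10, 100, "IE"),
                          self._report(50, 100, "O"))
        b = chisq_compare(self._report(50, 100, "IE"),
                          self._report(10, 100, "O"))
        assert a.statistic == pytest.approx(b.statistic)

    def test_large_group_difference_is_significant(self):
        """Proportions like 10.4% vs 2.8% at realistic sizes give p<0.001."""
        c = chisq_compare(self._report(83, 800, "IE"),
                          self._report(43, 1550, "O"))
        assert c.p_value < 0.001

    def test_zero_margin_flagged_degenerate(self):
        c = chisq_compare(self._report(0, 100, "IE"),
                          self._report(0, 100, "O"))
        assert c.degenerate
        assert np.isnan(c.p_value)

    def test_yates_correction_reduces_statistic(self):
        plain = chisq_compare(self._report(10, 100, "IE"),
                              self._report(20, 100, "O"), correction=False)
        yates = chisq_compare(self._report(10, 100, "IE"),
                              self._report(20, 100, "O"), correction=True)
        assert yates.statistic < plain.statistic


class TestQuantreg:
    def test_identical_groups_zero_coefficient(self):
        rng = np.random.default_rng(0)
        y = rng.lognormal(0, 0.5, 200)
        res = quantreg_group_test(y, y, tau=0.95, n_boot=200, seed=1)
        assert res.coef_group == 0.0
        assert res.p_value > 0.5

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        y_ie = rng.lognormal(0, 0.5, 300)
        res = quantreg_group_test(2.0 * y_ie, y_ie, tau=0.95, n_boot=10, seed=0)
        assert res.intercept + res.coef_group == pytest.approx(
            2.0 * res.intercept, rel=1e-12
        )

    def test_matches_brute_force_on_small_instances(self):
        """Exhaustive search over data-point breakpoints finds the same

        pinball-optimal fit for n <= 20 per group."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(3, 21))
            y_o = rng.lognormal(0, 0.6, n)
            y_ie = rng.lognormal(0.4, 0.8, n)
            tau = float(rng.choice([0.5, 0.8, 0.95]))
            res = quantreg_group_test(y_ie, y_o, tau=tau, n_boot=2, seed=0)
            fit_loss = (pinball_loss(y_o, res.intercept, tau)
                        + pinball_loss(y_ie, res.intercept + res.coef_group, tau))
            brute = min(pinball_loss(y_o, a, tau) + pinball_loss(y_ie, b, tau)
                        for a in y_o for b in y_ie)
            assert fit_loss == pytest.approx(brute, rel=1e-12)

    def test_matches_statsmodels_quantreg(self):
        """Independent check: linear-programming quantile regression from

        statsmodels finds the same coefficients."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        y_o = rng.lognormal(0, 0.5, 300)
        y_ie = rng.lognormal(0.3, 0.7, 300)
        y = np.concatenate([y_o, y_ie])
        X = sm.add_constant(np.r_[np.zeros(300), np.ones(300)])
        sm_fit = sm.QuantReg(y, X).fit(q=0.95)
        res = quantreg_group_test(y_ie, y_o, tau=0.95, n_boot=2, seed=0)
        assert res.intercept == pytest.approx(sm_fit.params[0], rel=1e-5)
        assert res.coef_group == pytest.approx(sm_fit.params[1], rel=1e-5)

    def test_fitted_quantiles_near_interpolated_percentiles(self, cortisol_deltas):
        """The order-statistic quantile of the fit differs from the

        interpolated 95th percentile by at most one inter-order-statistic
        gap."""
        dev_o = cortisol_deltas[cortisol_deltas["group"] == "O"]
        y = np.sort(dev_o["abs_dd"].to_numpy())
        q_fit = pinball_quantile(y, 0.95)
        k = np.searchsorted(y, q_fit)
        gap = y[min(k + 1, len(y) - 1)] - y[max(k - 1, 0)]
        from deltacheck import estimate_percentile
        assert abs(q_fit - estimate_percentile(y, 95)) <= gap + 1e-12
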