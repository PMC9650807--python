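import numpy as np
import pytest
from scipy import stats as sps

from midpass import (
    InsufficientDataError,
    SeparationError,
    fit_logistic_1d,
    mid_mean_change,
    mid_mean_difference_of_change,
    mid_predictive,
    mid_roc,
)
from conftest import DASH, make_pair, make_pairs


class TestMidRoc:
    def test_perfect_separation(self):
        pairs = make_pairs([-10, -8], [-1, 0])
        res = mid_roc(pairs, DASH, n_boot_cutoff=0, n_boot_auc=0)
        assert -8 < res.estimate < -1
        assert res.auxiliary["sensitivity"] == 1.0
        assert res.auxiliary["specificity"] == 1.0
        assert res.auxiliary["auc"] == 1.0
        assert res.n_improved == 2 and res.n_not_improved == 2

    def test_insufficient_group_reports_counts(self):
        pairs = make_pairs([-5], [0, 1])
        with pytest.raises(InsufficientDataError, match="improved=1"):
            mid_roc(pairs, DASH)

    def test_multi_point_improvers_count_as_improved(self):
        pairs = [make_pair(-9, 6, 4, pid="A"), make_pair(-8, 5, 4, pid="B")]
        pairs += make_pairs([], [0, 1])
        res = mid_roc(pairs, DASH, n_boot_cutoff=0, n_boot_auc=0)
        assert res.n_improved == 2

    def test_direction_flip_negates_estimate(self):
        rng = np.random.default_rng(3)
        imp = rng.normal(-10, 5, 80)
        not_imp = rng.normal(0, 5, 80)
        pairs = make_pairs(imp, not_imp)
        flipped = make_pairs(-imp, -not_imp, instrument=DASH.reflected())
        a = mid_roc(pairs, DASH, n_boot_cutoff=0, n_boot_auc=0)
        b = mid_roc(flipped, DASH.reflected(), n_boot_cutoff=0, n_boot_auc=0)
        assert b.estimate == pytest.approx(-a.estimate)
        assert b.auxiliary["auc"] == pytest.approx(a.auxiliary["auc"])

    def test_cluster_bootstrap_runs_and_differs_only_in_ci(self):
        rng = np.random.default_rng(5)
        pairs = make_pairs(rng.normal(-10, 5, 40), rng.normal(0, 5, 40))
        plain = mid_roc(pairs, DASH, n_boot_cutoff=100, n_boot_auc=0, seed=1)
        clustered = mid_roc(
            pairs, DASH, n_boot_cutoff=100, n_boot_auc=0, seed=1, cluster=True
        )
        assert clustered.estimate == plain.estimate
        assert np.isfinite(clustered.ci).all()


class TestMidMeanChange:
    def test_point_estimate_is_arithmetic_mean(self):
        pairs = make_pairs([-10, -12, -14], [0, 1])
        res = mid_mean_change(pairs, DASH)
        assert res.estimate == pytest.approx(-12.0)
        assert res.n_improved == 3

    def test_ci_matches_closed_form_t_interval(self):
        changes = [-10.0, -12.0, -14.0, -8.0]
        pairs = make_pairs(changes, [0, 1])
        res = mid_mean_change(pairs, DASH)
        x = np.array(changes)
        half = sps.t.ppf(0.975, 3) * x.std(ddof=1) / 2.0  # sd/sqrt(4)
        assert res.ci == pytest.approx((x.mean() - half, x.mean() + half))

    def test_only_one_point_improvers_enter(self):
        # a two-level improver must not contribute to the mean
        pairs = make_pairs([-10, -12], [0]) + [make_pair(-50, 6, 4, pid="X")]
        res = mid_mean_change(pairs, DASH)
        assert res.estimate == pytest.approx(-11.0)

    def test_empty_improver_group_errors(self):
        pairs = make_pairs([], [0, 1, 2])
        with pytest.raises(InsufficientDataError):
            mid_mean_change(pairs, DASH)


class TestMidMeanDifference:
    def test_point_estimate_is_difference_of_means(self):
        pairs = make_pairs([-10, -12], [-1, 1])
        res = mid_mean_difference_of_change(pairs, DASH)
        assert res.estimate == pytest.approx(-11.0)

    def test_ci_matches_welch_satterthwaite_closed_form(self):
        a = np.array([-10.0, -13.0, -7.0, -12.0])
        b = np.array([0.5, -1.0, 2.0, 0.0])
        pairs = make_pairs(a, b)
        res = mid_mean_difference_of_change(pairs, DASH)
        va, vb = a.var(ddof=1) / 4, b.var(ddof=1) / 4
        df = (va + vb) ** 2 / (va**2 / 3 + vb**2 / 3)
        half = sps.t.ppf(0.975, df) * np.sqrt(va + vb)
        delta = a.mean() - b.mean()
        assert res.ci == pytest.approx((delta - half, delta + half))

    def test_null_simulation_ci_covers_zero(self):
        rng = np.random.default_rng(11)
        covered = 0
        n_sim = 200
        for _ in range(n_sim):
            a = rng.normal(0, 5, 30)
            b = rng.normal(0, 5, 30)
            res = mid_mean_difference_of_change(make_pairs(a, b), DASH)
            covered += res.ci[0] <= 0.0 <= res.ci[1]
        assert covered / n_sim >= 0.90


class TestLogisticFit:
    def test_matches_statsmodels_mle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(13)
        x = rng.normal(0, 5, 300)
        y = (rng.random(300) < 1 / (1 + np.exp(-(0.3 - 0.4 * x)))).astype(float)
        c, b = fit_logistic_1d(x, y)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert c == pytest.approx(ref.params[0], abs=1e-6)
        assert b == pytest.approx(ref.params[1], abs=1e-6)

    def test_complete_separation_raises(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        with pytest.raises(SeparationError):
            fit_logistic_1d(np.sort(np.arange(20.0)), x)


class TestMidPredictive:
    def test_reduces_to_minus_c_over_b_at_half(self):
        rng = np.random.default_rng(17)
        pairs = make_pairs(rng.normal(-10, 5, 50), rng.normal(0, 5, 50))
        res = mid_predictive(pairs, DASH, n_boot=0)
        aux = res.auxiliary
        assert aux["proportion_improved"] == 0.5
        assert res.estimate == pytest.approx(-aux["intercept"] / aux["slope"])

    def test_prior_odds_offset_applied_when_unbalanced(self):
        rng = np.random.default_rng(19)
        pairs = make_pairs(rng.normal(-10, 5, 30), rng.normal(0, 5, 70))
        res = mid_predictive(pairs, DASH, n_boot=0)
        aux = res.auxiliary
        expected = (
            np.log(0.3 / 0.7) - aux["intercept"]
        ) / aux["slope"]
        assert res.estimate == pytest.approx(expected)

    def test_perfectly_separated_data_raises(self):
        pairs = make_pairs(np.arange(-20, -10.0), np.arange(0, 10.0))
        with pytest.raises(SeparationError):
            mid_predictive(pairs, DASH, n_boot=0)

    def test_too_few_pairs_rejected(self):
        pairs = make_pairs([-5, -6], [0, 1])
        with pytest.raises(InsufficientDataError):
            mid_predictive(pairs, DASH, n_boot=0)

    def test_bootstrap_ci_deterministic_and_brackets_estimate(self):
        rng = np.random.default_rng(23)
        pairs = make_pairs(rng.normal(-10, 5, 100), rng.normal(0, 5, 120))
        a = mid_predictive(pairs, DASH, n_boot=200, seed=7)
        b = mid_predictive(pairs, DASH, n_boot=200, seed=7)
        assert a.ci == b.ci
        assert a.ci[0] <= a.estimate <= a.ci[1]

    def test_direction_flip_negates_estimate(self):
        rng = np.random.default_rng(29)
        imp = rng.normal(-10, 5, 60)
        not_imp = rng.normal(0, 5, 60)
        a = mid_predictive(make_pairs(imp, not_imp), DASH, n_boot=0)
        b = mid_predictive(
            make_pairs(-imp, -not_imp, instrument=DASH.reflected()),
            DASH.reflected(),
            n_boot=0,
        )
        assert b.estimate == pytest.approx(-a.estimate, rel=1e-6)


class TestAffineEquivariance:
    def test_all_estimators_scale_with_the_instrument(self):
        from midpass import Instrument

        rng = np.random.default_rng(31)
        imp = rng.normal(-10, 5, 60)
        not_imp = rng.normal(0, 5, 60)
        a_scale = 0.1  # e.g. mapping a 0-100 scale onto 0-10
        scaled_inst = Instrument("dash10", 0, 10, "higher_is_worse", 0.1)
        pairs = make_pairs(imp, not_imp)
        scaled = make_pairs(a_scale * imp, a_scale * not_imp, instrument=scaled_inst)
        for fn, kwargs in (
            (mid_roc, {"n_boot_cutoff": 0, "n_boot_auc": 0}),
            (mid_mean_change, {}),
            (mid_mean_difference_of_change, {}),
            (mid_predictive, {"n_boot": 0}),
        ):
            full = fn(pairs, DASH, **kwargs)
            small = fn(scaled, scaled_inst, **kwargs)
            assert small.estimate == pytest.approx(
                a_scale * full.estimate, rel=1e-6, abs=1e-9
            )
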