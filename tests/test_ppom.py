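"""Partial proportional odds model: probabilities, fitting, inference, selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from bingeclass import (
    PartialProportionalOdds,
    PPOMSpec,
    category_probabilities,
    classify,
    cumulative_probability,
    fit_ppom,
    generate_cohort,
    published_classifier,
    select_items,
)
from bingeclass.ppom import _nll_and_grad
from bingeclass.survey import RETAINED_ITEMS
from conftest import CLUSTER_MEANS_RETAINED, numerical_gradient, sample_groups_from


class TestPublishedClassifier:
    def test_cumulative_probability_at_zero_items(self, published):
        # logistic(-5.87) by hand
        assert cumulative_probability(published, np.zeros(5), 2) == pytest.approx(
            expit(-5.87), abs=1e-10
        )
        assert cumulative_probability(published, np.zeros(5), 2) == pytest.approx(
            0.00281, abs=2e-5
        )

    def test_group4_linear_predictor_hand_arithmetic(self, published):
        x = CLUSTER_MEANS_RETAINED[4]
        # independent hand computation of the >=4 equation
        eta = (-8.46 + 0.43 * x[0] - 0.13 * x[1] + 0.34 * x[2]
               + 0.02 * x[3] - 0.34 * x[4])
        assert eta == pytest.approx(4.406, abs=5e-3)
        assert published.linear_predictor([x])[0, 2] == pytest.approx(eta, abs=1e-10)
        assert cumulative_probability(published, x, 4) == pytest.approx(0.988, abs=1e-3)

    def test_threshold_out_of_range_rejected(self, published):
        for j in (1, 5):
            with pytest.raises(ValueError):
                cumulative_probability(published, np.zeros(5), j)

    def test_category_probabilities_at_zero_items(self, published):
        probs = category_probabilities(published, np.zeros(5))
        assert probs[0] == pytest.approx(0.9972, abs=2e-4)
        assert probs[1:].sum() < 0.003

    def test_group1_means_classified_lowest(self, published):
        x = CLUSTER_MEANS_RETAINED[1]
        assert published.linear_predictor([x])[0, 0] == pytest.approx(-3.587, abs=2e-3)
        assert category_probabilities(published, x).argmax() == 0

    @pytest.mark.parametrize("group", [1, 2, 3, 4])
    def test_cluster_mean_vectors_classified_to_own_group(self, published, group):
        assert classify(published, CLUSTER_MEANS_RETAINED[group]).index == group

    def test_probability_simplex_property(self, published):
        rng = np.random.default_rng(0)
        X = np.column_stack([
            rng.integers(0, 5, 200),
            rng.uniform(0, 6, 200),
            rng.integers(0, 60, 200),
            rng.uniform(0, 10, 200),
            rng.uniform(0, 10, 200),
        ]).astype(float)
        probs, _ = published.category_proba(X)
        assert np.all(probs >= 0) and np.all(probs <= 1)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        cum = published.cumulative_proba(X)
        assert np.all((cum > 0) & (cum < 1))

    def test_tie_breaks_toward_lower_group(self):
        # two-level model with P(y>=2)=0.5 at x=0: exact tie, group 1 wins
        model = PartialProportionalOdds.from_coefficients([0.0], {"x": 1.0}, n_levels=2)
        assert model.predict([[0.0]])[0] == 1

    def test_full_precision_set_available(self):
        alt = published_classifier("table-full-precision")
        assert alt.coefs_["six_drink_frequency"] == pytest.approx(0.42646)
        np.testing.assert_allclose(alt.intercepts_, [-5.87, -7.37, -8.46])
        with pytest.raises(ValueError):
            published_classifier("nope")


class TestSpec:
    def test_structure_validation(self):
        with pytest.raises(ValueError):
            PPOMSpec((), (), 4)
        with pytest.raises(ValueError):
            PPOMSpec(("a",), (True,), 1)
        with pytest.raises(ValueError):
            PPOMSpec(("a", "b"), (True,), 4)

    def test_param_layout(self):
        spec = PPOMSpec.from_names(["a", "b"], {"a": True, "b": False}, 4)
        assert spec.n_params() == 3 + 1 + 3
        alpha, B = spec.unpack(np.arange(7, dtype=float))
        np.testing.assert_allclose(alpha, [0, 1, 2])
        np.testing.assert_allclose(B[0], [3, 3, 3])  # shared
        np.testing.assert_allclose(B[1], [4, 5, 6])  # per threshold

    def test_from_coefficients_requires_matching_intercepts(self):
        with pytest.raises(ValueError):
            PartialProportionalOdds.from_coefficients([0.0, 1.0], {"x": 1.0}, n_levels=4)


class TestFitting:
    def test_two_level_model_equals_binary_logistic(self):
        """With K=2 the PPOM collapses to plain logistic regression."""
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        n = 400
        X = rng.normal(0, 1, (n, 2))
        eta = -0.3 + 0.8 * X[:, 0] - 0.5 * X[:, 1]
        y = 1 + (rng.random(n) < expit(eta)).astype(int)
        fit = fit_ppom(X, y, predictors=["a", "b"],
                       proportional={"a": True, "b": True}, n_levels=2)
        sm_fit = sm.Logit((y == 2).astype(int), sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(
            [fit.intercepts_[0], fit.coefs_["a"], fit.coefs_["b"]],
            sm_fit.params, atol=1e-4,
        )

    def test_gradient_matches_numerical_differentiation(self):
        """Analytic score equals finite differences at 20 random valid points."""
        rng = np.random.default_rng(12)
        spec = PPOMSpec.from_names(["a", "b"], {"a": True, "b": False}, 4)
        X = rng.normal(0, 1, (60, 2))
        y = rng.integers(1, 5, 60)
        checked = 0
        while checked < 20:
            theta = np.concatenate([
                np.sort(rng.normal(0, 1, 3))[::-1], rng.normal(0, 0.3, 4)
            ])
            # stay in the smooth interior (valid probability region)
            alpha, B = spec.unpack(theta)
            eta = alpha + X @ B
            s = expit(eta)
            probs = np.column_stack([1 - s[:, 0], s[:, 0] - s[:, 1],
                                     s[:, 1] - s[:, 2], s[:, 2]])
            if probs.min() < 1e-4:
                continue
            ana = _nll_and_grad(theta, X, y, spec)[1]
            num = numerical_gradient(
                lambda t: _nll_and_grad(t, X, y, spec)[0], theta
            )
            np.testing.assert_allclose(ana, num, rtol=1e-5, atol=1e-5)
            checked += 1

    def test_parameter_recovery_from_published_equations(self, published):
        """Slopes regenerate within sampling error; drunkenness z dominates."""
        cohort, _ = generate_cohort(n=5000, seed=1)
        X = cohort[list(RETAINED_ITEMS)]
        y = sample_groups_from(published, X, seed=1)
        fit = fit_ppom(X, y, predictors=list(RETAINED_ITEMS))
        assert fit.converged_
        # shared coefficients are well identified
        assert fit.coefs_["six_drink_frequency"] == pytest.approx(0.43, abs=0.1)
        assert fit.coefs_["drunkenness_frequency"] == pytest.approx(0.34, abs=0.1)
        # every slope within 3 SE of its generating value
        wt = fit.wald_table().set_index(["predictor", "scope"])
        truth = published.coefs_
        pos = 0
        for p in RETAINED_ITEMS:
            true_vals = np.atleast_1d(truth[p])
            rows = wt.loc[p] if isinstance(wt.loc[p], pd.DataFrame) else wt.loc[[p]]
            est = rows["coefficient"].to_numpy()
            se = rows["se"].to_numpy()
            assert np.all(np.abs(est - true_vals) < 3 * se + 1e-9), p
        assert np.abs(fit.intercepts_ - published.intercepts_).max() < 1.0
        zmax = fit.wald_table().groupby("predictor").z.apply(lambda s: s.abs().max())
        assert zmax.idxmax() == "drunkenness_frequency"

    def test_loglik_at_optimum_beats_generating_parameters(self, published):
        cohort, _ = generate_cohort(n=800, seed=2)
        X = cohort[list(RETAINED_ITEMS)]
        y = sample_groups_from(published, X, seed=2)
        fit = fit_ppom(X, y, predictors=list(RETAINED_ITEMS))
        nll_true, _ = _nll_and_grad(
            published.params_, X.to_numpy(float), y, published.spec_
        )
        assert fit.loglik_ >= -nll_true - 1e-6

    def test_proportional_truth_yields_near_equal_threshold_coefficients(self):
        """Fitting a non-proportional spec to proportional-odds data shrinks
        the per-threshold coefficients together."""
        rng = np.random.default_rng(6)
        n = 4000
        X = rng.normal(0, 1.5, (n, 1))
        alpha = np.array([1.0, -0.5, -2.0])
        eta = alpha + 0.7 * X
        s = expit(eta)
        probs = np.column_stack([1 - s[:, 0], s[:, 0] - s[:, 1],
                                 s[:, 1] - s[:, 2], s[:, 2]])
        probs = np.clip(probs, 0, None)
        probs /= probs.sum(1, keepdims=True)
        u = rng.random(n)
        y = 1 + (u[:, None] > probs.cumsum(1)[:, :-1]).sum(1)
        fit = fit_ppom(X, y, predictors=["x"], proportional={"x": False})
        coefs = fit.coefs_["x"]
        wt = fit.wald_table()
        ses = wt[wt.predictor == "x"].se.to_numpy()
        assert np.abs(coefs - 0.7).max() < 3 * ses.max()
        assert coefs.max() - coefs.min() < 4 * ses.max()

    def test_empty_group_rejected(self):
        X = np.random.default_rng(0).normal(0, 1, (30, 1))
        y = np.array([1, 2, 3] * 10)  # group 4 absent
        with pytest.raises(ValueError, match="group 4"):
            fit_ppom(X, y, predictors=["x"])


class TestWaldTable:
    def test_z_and_p_arithmetic(self, published):
        """z = coef/SE against the printed Wald-table arithmetic."""
        model = PartialProportionalOdds.from_coefficients(
            [-1.0], {"drunk": 0.33708, "six": 0.42646, "zero": 0.0}, n_levels=2
        )
        model.se_ = np.array([0.5, 0.02394, 0.14719, 0.1])
        model.z_ = model.params_ / model.se_
        from scipy.stats import norm
        model.p_ = 2 * norm.sf(np.abs(model.z_))
        table = model.wald_table()
        drunk = table[table.predictor == "drunk"].iloc[0]
        assert drunk.z == pytest.approx(14.083, abs=0.01)
        assert drunk.p < 0.001
        six = table[table.predictor == "six"].iloc[0]
        assert six.z == pytest.approx(2.897, abs=0.005)
        assert six.p < 0.01
        zero = table[table.predictor == "zero"].iloc[0]
        assert zero.z == 0 and zero.p == pytest.approx(1.0)

    def test_scope_column_layout(self, published):
        cohort, _ = generate_cohort(n=600, seed=3)
        X = cohort[list(RETAINED_ITEMS)]
        y = sample_groups_from(published, X, seed=3)
        fit = fit_ppom(X, y, predictors=list(RETAINED_ITEMS))
        table = fit.wald_table()
        shared = table[table.predictor == "drunkenness_frequency"]
        assert list(shared.scope) == [">=2, >=3, =4"]
        per = table[table.predictor == "consumption_speed"]
        assert list(per.scope) == [">=2", ">=3", "=4"]


class TestSelectItems:
    def test_null_candidates_dropped(self, published):
        """Items with zero true coefficient are dropped at the 0.05 level."""
        cohort, _ = generate_cohort(n=4000, seed=3)
        rng = np.random.default_rng(33)
        X = cohort[list(RETAINED_ITEMS)].copy()
        y = sample_groups_from(published, X, seed=3)
        X["null_a"] = rng.normal(0, 1, len(X))
        X["null_b"] = rng.normal(0, 1, len(X))
        retained, trail = select_items(X, y)
        assert "null_a" not in retained and "null_b" not in retained
        assert set(RETAINED_ITEMS) <= set(retained)

    def test_correlated_block_keeps_strongest(self, published):
        """Near-duplicate noise items collapse to nothing; the retained set
        matches the published five items."""
        cohort, _ = generate_cohort(n=4000, seed=4)
        X = cohort[
            ["consumption_frequency", "drinks_typical_day"] + list(RETAINED_ITEMS)
        ].copy()
        y = sample_groups_from(published, cohort[list(RETAINED_ITEMS)], seed=4)
        retained, trail = select_items(X, y)
        assert retained == list(RETAINED_ITEMS)

    def test_redundant_shadow_of_dominant_item_dropped(self, published):
        cohort, _ = generate_cohort(n=2000, seed=5)
        X = cohort[list(RETAINED_ITEMS)].copy()
        y = sample_groups_from(published, X, seed=5)
        rng = np.random.default_rng(55)
        # strongly correlated, conditionally uninformative shadow
        X["drunk_shadow"] = X["drunkenness_frequency"] + rng.normal(0, 1, len(X))
        retained, trail = select_items(X, y)
        assert "drunkenness_frequency" in retained
        assert "drunk_shadow" not in retained

    def test_correlated_block_keeps_member_with_strongest_evidence(self):
        """Two correlated items that each carry independent signal collapse
        to the stronger one by the collinearity rule."""
        rng = np.random.default_rng(21)
        n = 3000
        z = rng.normal(0, 1, n)
        x1 = z + rng.normal(0, 0.55, n)
        x2 = z + rng.normal(0, 0.55, n)
        eta = np.array([1.0, -0.5, -2.0]) + (1.1 * x1 + 0.7 * x2)[:, None]
        s = expit(eta)
        probs = np.column_stack([1 - s[:, 0], s[:, 0] - s[:, 1],
                                 s[:, 1] - s[:, 2], s[:, 2]])
        y = 1 + (rng.random(n)[:, None] > probs.cumsum(1)[:, :-1]).sum(1)
        X = pd.DataFrame({"x1": x1, "x2": x2})
        assert X.corr().loc["x1", "x2"] > 0.7
        retained, trail = select_items(
            X, y, proportional={"x1": True, "x2": True}
        )
        assert retained == ["x1"]
        assert "correlated block" in trail[trail.item == "x2"].reason.iloc[-1]

    def test_single_significant_candidate_returned(self):
        rng = np.random.default_rng(9)
        n = 1500
        x = rng.normal(0, 2, n)
        eta = np.column_stack([1.5 + x, -0.5 + x, -2.5 + x])
        s = expit(eta)
        probs = np.column_stack([1 - s[:, 0], s[:, 0] - s[:, 1],
                                 s[:, 1] - s[:, 2], s[:, 2]])
        y = 1 + (rng.random(n)[:, None] > probs.cumsum(1)[:, :-1]).sum(1)
        X = pd.DataFrame({"x": x})
        retained, _ = select_items(X, y, proportional={"x": True})
        assert retained == ["x"]

    def test_all_dropped_raises_with_diagnostics(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame({"noise": rng.normal(0, 1, 600)})
        y = rng.integers(1, 5, 600)
        with pytest.raises(ValueError, match="all candidate items dropped"):
            select_items(X, y, proportional={"noise": True})
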