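"""Logistic/IRLS, stepwise-AIC and CART checked against closed forms,
statsmodels/sklearn oracles and brute-force searches."""

import math

import numpy as np
import pandas as pd
import pytest

from pdxms.models import (
    _prune_at,
    _walk,
    design_matrix,
    fit_cart,
    fit_logistic,
    prune_tree,
    scaled_odds_ratio,
    stepwise_backward_aic,
    univariate_screen,
)
from pdxms.synthdata import CohortGenSpec, expand_counts, generate_cohort

SUBTYPE = {"HER2+": (20, 1), "HR+": (130, 4), "HR+/HER2+": (30, 1),
           "TNBC": (90, 44)}
HG = {"2": (139, 3), "3": (131, 47)}
NAC = {"no": (177, 12), "yes": (93, 38)}
HG_NAC = {"2": (41, 3), "3": (52, 35)}


def two_by_two_fit(a, b, c, d):
    """Fit exposure yes/no on counts: exposed a success / b failure,
    unexposed c success / d failure; returns (fit, closed-form beta, se)."""
    records = expand_counts({"yes": (b, a), "no": (d, c)}, variable="x")
    fit = fit_logistic(records, "engrafted", ["x"], reference={"x": "no"})
    beta = math.log((a / b) / (c / d))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return fit, beta, se


class TestLogistic:
    @pytest.mark.parametrize("a,b,c,d", [
        (44, 90, 1, 20), (38, 93, 12, 177), (47, 131, 3, 139),
        (35, 52, 3, 41), (7, 3, 2, 8), (10, 5, 5, 10),
    ])
    def test_two_by_two_matches_closed_form(self, a, b, c, d):
        fit, beta, se = two_by_two_fit(a, b, c, d)
        got_beta, got_se = fit.coef_for("x[yes]")
        assert got_beta == pytest.approx(beta, abs=1e-6)
        assert got_se == pytest.approx(se, abs=1e-6)

    def test_published_contingency_odds_ratios(self):
        """The five univariate odds ratios derivable from the printed
        outcome-by-category counts reproduce at two decimals."""
        subtype = fit_logistic(expand_counts(SUBTYPE, variable="subtype"),
                               "engrafted", ["subtype"],
                               reference={"subtype": "HER2+"})
        assert round(math.exp(subtype.coef_for("subtype[TNBC]")[0]), 2) == 9.78
        assert round(math.exp(subtype.coef_for("subtype[HR+]")[0]), 2) == 0.62
        hg = fit_logistic(expand_counts(HG, variable="hg"), "engrafted",
                          ["hg"])
        assert round(math.exp(hg.coef_for("hg[3]")[0]), 2) == 16.62
        nac = fit_logistic(expand_counts(NAC, variable="nac"), "engrafted",
                           ["nac"])
        assert round(math.exp(nac.coef_for("nac[yes]")[0]), 2) == 6.03
        hg_nac = fit_logistic(expand_counts(HG_NAC, variable="hg"),
                              "engrafted", ["hg"])
        assert round(math.exp(hg_nac.coef_for("hg[3]")[0]), 2) == 9.20

    def test_wald_ci_of_tnbc_or(self):
        fit = fit_logistic(expand_counts(SUBTYPE, variable="subtype"),
                           "engrafted", ["subtype"],
                           reference={"subtype": "HER2+"})
        j = fit.names.index("subtype[TNBC]")
        lo, hi = fit.conf_int[j]
        assert round(lo, 2) == 1.27
        assert round(hi, 2) == 75.23

    def test_matches_statsmodels_on_mixed_design(self, small_cohort):
        sm = pytest.importorskip("statsmodels.api")
        table = small_cohort.table
        terms = ["age", "ki67", "nac", "NP"]
        fit = fit_logistic(table, "engrafted", terms)
        design = design_matrix(table, terms)
        res = sm.Logit(table["engrafted"].to_numpy(float),
                       design.matrix).fit(disp=0)
        assert np.allclose(fit.coef, res.params, atol=1e-6)
        assert np.allclose(fit.se, res.bse, atol=1e-6)
        assert fit.loglik == pytest.approx(res.llf, abs=1e-6)
        assert fit.aic == pytest.approx(res.aic, abs=1e-6)

    def test_null_covariate_near_zero(self):
        rng = np.random.default_rng(3)
        frame = pd.DataFrame({"x": rng.normal(size=4000),
                              "y": rng.integers(0, 2, size=4000)})
        fit = fit_logistic(frame, "y", ["x"])
        beta, se = fit.coef_for("x")
        assert abs(beta) < 3 * se

    def test_aic_consistent_with_loglik(self, small_cohort):
        fit = fit_logistic(small_cohort.table, "engrafted", ["ki67", "nac"])
        k = len(fit.coef)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * k, abs=1e-8)

    def test_separation_flagged_not_fatal(self):
        frame = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)],
                              "y": np.r_[np.zeros(20), np.ones(20)].astype(int)})
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_logistic(frame, "y", ["x"])
        assert fit.separation

    def test_single_class_outcome_rejected(self):
        frame = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [1, 1, 1]})
        with pytest.raises(ValueError):
            fit_logistic(frame, "y", ["x"])

    def test_aliased_column_dropped_with_warning(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame({"x": rng.normal(size=200)})
        frame["x2"] = 2.0 * frame["x"]
        frame["y"] = (rng.uniform(size=200) < 0.4).astype(int)
        with pytest.warns(UserWarning, match="aliased"):
            fit = fit_logistic(frame, "y", ["x", "x2"])
        assert fit.dropped == ["x2"]


class TestScreenAndStepwise:
    def test_screen_keeps_strong_drops_null(self):
        rng = np.random.default_rng(8)
        n = 1000
        strong = rng.normal(size=n)
        noise = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(-0.5 + 1.2 * strong)))
        frame = pd.DataFrame({"strong": strong, "noise": noise,
                              "y": (rng.uniform(size=n) < p).astype(int)})
        fits, candidates = univariate_screen(frame, "y", ["strong", "noise"])
        assert "strong" in candidates
        assert fits["strong"].term_p("strong") < 0.2
        # a genuinely null covariate with p >= 0.2 must be excluded
        if fits["noise"].term_p("noise") >= 0.2:
            assert "noise" not in candidates

    def test_screen_records_failures(self):
        frame = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0],
                              "flat": [1.0, 1.0, 1.0, 1.0],
                              "y": [0, 1, 0, 1]})
        fits, _ = univariate_screen(frame, "y", ["x", "flat"])
        assert isinstance(fits["x"], object)

    def test_strong_predictor_retained(self):
        rng = np.random.default_rng(9)
        n = 800
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-1.5 * x))
        frame = pd.DataFrame({"x": x,
                              "y": (rng.uniform(size=n) < p).astype(int)})
        final, trace = stepwise_backward_aic(frame, "y", ["x"])
        assert final.terms == ["x"]
        assert len(trace) == 1

    def test_aic_monotone_along_trace(self, small_cohort):
        table = small_cohort.table
        candidates = ["age", "ki67", "nac", "hg", "size_cm", "NP", "SP",
                      "TILP", "n_pos_ln"]
        final, trace = stepwise_backward_aic(table, "engrafted", candidates)
        aics = trace["aic"].to_numpy()
        assert (np.diff(aics) < 0).all()
        full = fit_logistic(table, "engrafted", candidates)
        assert final.aic <= full.aic + 1e-10

    def test_fixed_point_returned_unchanged(self):
        rng = np.random.default_rng(10)
        n = 2000
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(1.0 * x1 + 1.0 * x2)))
        frame = pd.DataFrame({"x1": x1, "x2": x2,
                              "y": (rng.uniform(size=n) < p).astype(int)})
        final, trace = stepwise_backward_aic(frame, "y", ["x1", "x2"])
        assert set(final.terms) == {"x1", "x2"}
        assert trace["removed"].isna().all()


class TestScaledOdds:
    def test_zero_beta_gives_unit_or(self):
        frame = pd.DataFrame({"x": [0.0, 1.0] * 50, "y": [0, 1, 1, 0] * 25})
        fit = fit_logistic(frame, "y", ["x"])
        fit.coef[fit.names.index("x")] = 0.0
        or_, _ = scaled_odds_ratio(fit, "x", 123.0)
        assert or_ == 1.0

    def test_delta_one_is_identity(self, small_cohort):
        fit = fit_logistic(small_cohort.table, "engrafted", ["NP"])
        or_, ci = scaled_odds_ratio(fit, "NP", 1.0)
        j = fit.names.index("NP")
        assert or_ == pytest.approx(fit.odds_ratios[j], abs=1e-12)
        assert ci == pytest.approx(tuple(fit.conf_int[j]), abs=1e-12)

    def test_thousand_unit_scaling_algebra(self, small_cohort):
        fit = fit_logistic(small_cohort.table, "engrafted", ["NP"])
        fit.coef[fit.names.index("NP")] = math.log(1.058) / 1000.0
        or_, _ = scaled_odds_ratio(fit, "NP", 1000.0)
        assert or_ == pytest.approx(1.058, abs=1e-12)

    def test_unknown_term_rejected(self, small_cohort):
        fit = fit_logistic(small_cohort.table, "engrafted", ["NP"])
        with pytest.raises(KeyError):
            scaled_odds_ratio(fit, "nonexistent", 1.0)


# ---------------------------------------------------------------------------
# CART


def brute_force_root_split(frame, y, variables, minbucket=1):
    """Exhaustive search over every variable and admissible threshold."""
    n = len(y)
    n1 = y.sum()
    parent = 2.0 * n1 * (n - n1) / n
    best = None
    for var in variables:
        x = frame[var].to_numpy(dtype=float)
        for thr in np.unique(x)[:-1]:
            left = x <= thr
            nl, nr = left.sum(), n - left.sum()
            if nl < minbucket or nr < minbucket:
                continue
            l1, r1 = y[left].sum(), n1 - y[left].sum()
            child = (2.0 * l1 * (nl - l1) / nl + 2.0 * r1 * (nr - r1) / nr)
            dec = parent - child
            if best is None or dec > best[0] + 1e-12:
                best = (dec, var, thr)
    return best


class TestCart:
    def test_perfect_separator_single_split(self):
        frame = pd.DataFrame({"x": np.r_[np.zeros(30), np.ones(30)],
                              "y": np.r_[np.zeros(30), np.ones(30)].astype(int)})
        tree = fit_cart(frame, "y", ["x"], xval_folds=0)
        assert tree.n_splits() == 1
        assert (tree.predict(frame) == frame["y"].to_numpy()).all()

    def test_root_split_matches_exhaustive_search(self):
        rng = np.random.default_rng(12)
        frame = pd.DataFrame({
            "a": rng.normal(size=20), "b": rng.normal(size=20),
            "c": rng.integers(0, 5, size=20).astype(float)})
        y = (rng.uniform(size=20) < 0.5).astype(int)
        frame["y"] = y
        tree = fit_cart(frame, "y", ["a", "b", "c"], minsplit=2, minbucket=1,
                        xval_folds=0)
        dec, var, thr = brute_force_root_split(frame, y, ["a", "b", "c"])
        root = tree.root
        assert root.split_var == var
        x = frame[var].to_numpy(float)
        assert root.threshold == pytest.approx(
            (thr + np.unique(x)[np.searchsorted(np.unique(x), thr) + 1]) / 2)
        assert root.improve == pytest.approx(dec, abs=1e-9)

    def test_root_split_matches_sklearn(self, small_cohort):
        sklearn_tree = pytest.importorskip("sklearn.tree")
        table = small_cohort.table
        variables = ["age", "ki67", "size_cm", "NP", "SP", "TILP"]
        tree = fit_cart(table, "engrafted", variables, xval_folds=0)
        clf = sklearn_tree.DecisionTreeClassifier(
            criterion="gini", max_depth=1, min_samples_split=20,
            min_samples_leaf=7, random_state=0)
        clf.fit(table[variables], table["engrafted"])
        assert variables[clf.tree_.feature[0]] == tree.root.split_var
        assert clf.tree_.threshold[0] == pytest.approx(tree.root.threshold,
                                                       rel=1e-9)

    def test_categorical_split_by_rate_ordering(self):
        frame = pd.DataFrame({
            "g": ["a"] * 20 + ["b"] * 20 + ["c"] * 20,
            "y": [1] * 18 + [0] * 2 + [0] * 20 + [1] * 10 + [0] * 10})
        tree = fit_cart(frame, "y", ["g"], xval_folds=0)
        root = tree.root
        assert root.split_kind == "cat"
        # 'b' (rate 0) must be separated from 'a' (rate 0.9); the split
        # never groups the extreme-rate levels together
        assert ("a" in root.left_levels) != ("b" in root.left_levels)

    def test_cp_infinite_prunes_to_root(self, small_cohort):
        tree = fit_cart(small_cohort.table, "engrafted",
                        ["ki67", "NP", "age"], xval_folds=0)
        pruned = prune_tree(tree, np.inf)
        assert pruned.n_splits() == 0

    def test_cp_zero_is_noop(self, small_cohort):
        tree = fit_cart(small_cohort.table, "engrafted",
                        ["ki67", "NP", "age"], xval_folds=0)
        pruned = prune_tree(tree, 0.0)
        assert pruned.n_splits() == tree.n_splits()

    def test_rel_error_nonincreasing_and_training_error_ordering(
            self, small_cohort):
        tree = fit_cart(small_cohort.table, "engrafted",
                        ["age", "ki67", "subtype", "hg", "nac", "size_cm",
                         "NP", "SP", "ICP"], seed=3)
        tab = tree.cp_table.sort_values("n_splits")
        assert (np.diff(tab["rel_error"].to_numpy()) <= 1e-12).all()
        pruned = prune_tree(tree, 0.03)
        y = small_cohort.table["engrafted"].to_numpy(int)
        data = small_cohort.table
        err_full = (tree.predict(data) != y).mean()
        err_pruned = (pruned.predict(data) != y).mean()
        assert err_pruned >= err_full - 1e-12

    def test_importances_sum_to_hundred(self, small_cohort):
        tree = fit_cart(small_cohort.table, "engrafted",
                        ["age", "ki67", "NP", "SP"], xval_folds=0)
        assert sum(tree.variable_importance.values()) == pytest.approx(
            100.0, abs=0.1)

    def test_child_counts_sum_to_parent(self, small_cohort):
        tree = fit_cart(small_cohort.table, "engrafted",
                        ["age", "ki67", "NP", "SP"], xval_folds=0)
        for node in _walk(tree.root):
            if not node.is_leaf:
                assert np.array_equal(node.counts,
                                      node.left.counts + node.right.counts)

    def test_weakest_link_prune_matches_sequence(self, small_cohort):
        """Pruning the fitted tree at any CP of its own table yields the
        same tree as recomputing the weakest-link sequence from scratch."""
        tree = fit_cart(small_cohort.table, "engrafted",
                        ["age", "ki67", "NP", "SP", "size_cm"],
                        xval_folds=0)
        root_risk = max(tree.root.risk, 1)
        for cp in tree.cp_table["CP"]:
            via_api = prune_tree(tree, cp + 1e-9)
            direct = _prune_at(tree.root, cp + 1e-9, root_risk)
            api_splits = sorted((nd.split_var, nd.threshold)
                                for nd in _walk(via_api.root)
                                if not nd.is_leaf)
            direct_splits = sorted((nd.split_var, nd.threshold)
                                   for nd in _walk(direct)
                                   if not nd.is_leaf)
            assert api_splits == direct_splits

    def test_single_class_outcome_gives_stump(self):
        frame = pd.DataFrame({"x": np.arange(30.0), "y": [0] * 30})
        with pytest.warns(UserWarning, match="single class"):
            tree = fit_cart(frame, "y", ["x"])
        assert tree.n_splits() == 0
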