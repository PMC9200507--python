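import math

import numpy as np
import pandas as pd
import pytest

from mmaselect import DataTable, NBConfig, fit_nb, predict, predict_proba


def make_table(columns: dict, kinds: tuple, labels) -> DataTable:
    return DataTable(pd.DataFrame(columns), kinds, np.asarray(labels), ("0", "1"))


def brute_force_posteriors(model, table) -> np.ndarray:
    """Independent check: direct probability products, no logs."""
    out = np.zeros((table.n_rows, 2))
    core = model.core
    for i in range(table.n_rows):
        for c in (0, 1):
            p = core.priors[c]
            for j, name in enumerate(model.numeric_columns):
                x = float(table.features[name][i])
                mu, var = core.means[c, j], core.variances[c, j]
                p *= math.exp(-((x - mu) ** 2) / (2 * var)) / math.sqrt(
                    2 * math.pi * var
                )
            for j, name in enumerate(model.categorical_columns):
                level = table.features[name][i]
                code = model.cat_levels[j].index(level)
                p *= math.exp(core.cat_log_probs[j][c, code])
            out[i, c] = p
        out[i] /= out[i].sum()
    return out


class TestFit:
    def test_balanced_split_gives_half_priors(self, tiny_numeric_table):
        model = fit_nb(tiny_numeric_table)
        assert np.allclose(model.class_priors, [0.5, 0.5])

    def test_laplace_smoothed_level_probability(self):
        # class 0: three rows, all level "yes"; alpha=1, 2 levels observed
        table = make_table(
            {"f": ["yes", "yes", "yes", "no", "yes", "no"]},
            ("categorical",),
            [0, 0, 0, 1, 1, 1],
        )
        model = fit_nb(table, NBConfig(alpha=1.0))
        yes_code = model.cat_levels[0].index("yes")
        p_yes_given_0 = np.exp(model.core.cat_log_probs[0][0, yes_code])
        assert p_yes_given_0 == pytest.approx((3 + 1) / (3 + 2))

    def test_level_probabilities_sum_to_one_per_class(self, planted_table):
        table, _ = planted_table
        model = fit_nb(table)
        for log_table in model.core.cat_log_probs:
            assert np.allclose(np.exp(log_table).sum(axis=1), 1.0)

    def test_constant_feature_gets_variance_floor(self):
        table = make_table(
            {"c": [2.0] * 6, "x": [0.0, 0.1, 0.2, 1.0, 1.1, 1.2]},
            ("numeric", "numeric"),
            [0, 0, 0, 1, 1, 1],
        )
        model = fit_nb(table, NBConfig(var_floor=1e-9))
        assert np.all(model.core.variances[:, 0] == 1e-9)
        # prediction still finite and normalized
        probs = predict_proba(model, table)
        assert np.all(np.isfinite(probs))

    def test_single_class_training_rejected(self):
        table = make_table({"x": [1.0, 2.0]}, ("numeric",), [0, 0])
        table.class_names = ("0", "1")
        with pytest.raises(Exception, match="class"):
            fit_nb(table)


class TestPredict:
    def test_symmetric_model_midpoint_is_fifty_fifty(self):
        table = make_table(
            {"x": [-1.0, -2.0, -3.0, 1.0, 2.0, 3.0]},
            ("numeric",),
            [0, 0, 0, 1, 1, 1],
        )
        model = fit_nb(table)
        midpoint = make_table({"x": [0.0]}, ("numeric",), [0])
        probs = predict_proba(model, midpoint)
        assert probs[0] == pytest.approx([0.5, 0.5])

    def test_posteriors_normalized(self, planted_table):
        table, _ = planted_table
        model = fit_nb(table)
        probs = predict_proba(model, table)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_hand_computed_single_categorical_posterior(self):
        """priors (0.6, 0.4), P(level|c0)=0.8, P(level|c1)=0.3 ->
        posterior c0 = 0.48 / (0.48 + 0.12) = 0.8 (alpha=0 for exactness)."""
        f = ["a"] * 48 + ["b"] * 12 + ["a"] * 12 + ["b"] * 28
        y = [0] * 60 + [1] * 40
        table = make_table({"f": f}, ("categorical",), y)
        model = fit_nb(table, NBConfig(alpha=1e-12))
        row = make_table({"f": ["a"]}, ("categorical",), [0])
        probs = predict_proba(model, row)
        assert probs[0, 0] == pytest.approx(0.8, abs=1e-6)

    def test_unseen_level_never_zero_probability(self):
        table = make_table(
            {"f": ["a", "a", "b", "b"]}, ("categorical",), [0, 0, 1, 1]
        )
        model = fit_nb(table, NBConfig(alpha=1.0))
        unseen = make_table({"f": ["zzz"]}, ("categorical",), [0])
        probs = predict_proba(model, unseen)
        assert np.all(probs > 0)
        assert np.isfinite(probs).all()

    @pytest.mark.parametrize(
        "labels,expected",
        [([0, 0, 1, 1], 0), ([0, 1, 1, 1], 1)],  # tie -> larger prior, then lower idx
    )
    def test_tie_breaks_by_prior_then_lower_index(self, labels, expected):
        # constant feature: identical likelihoods for both classes at alpha=0
        table = make_table({"f": ["a"] * 4}, ("categorical",), labels)
        model = fit_nb(table, NBConfig(alpha=0.0))
        row = make_table({"f": ["a"]}, ("categorical",), [0])
        assert predict(model, row)[0] == expected

    def test_log_space_survives_thousand_features(self):
        rng = np.random.default_rng(0)
        n, d = 30, 1000
        X = rng.normal(size=(n, d))
        y = rng.integers(0, 2, size=n)
        y[:2] = [0, 1]
        table = make_table(
            {f"x{j}": X[:, j] for j in range(d)}, ("numeric",) * d, y
        )
        model = fit_nb(table)
        probs = predict_proba(model, table)
        assert np.all(np.isfinite(probs))
        assert np.allclose(probs.sum(axis=1), 1.0)


class TestAgainstIndependentImplementations:
    def test_matches_brute_force_products(self, mixed_table):
        from mmaselect.preprocess import impute_missing

        table = impute_missing(mixed_table)
        model = fit_nb(table)
        ours = predict_proba(model, table)
        brute = brute_force_posteriors(model, table)
        assert np.allclose(ours, brute, atol=1e-9)

    def test_matches_sklearn_gaussian_nb_on_numeric_data(self, planted_table):
        sklearn_nb = pytest.importorskip("sklearn.naive_bayes")
        table, _ = planted_table
        num_cols = [
            n for n, k in zip(table.column_names, table.column_kinds) if k == "numeric"
        ]
        X = table.features[num_cols].to_numpy(dtype=float)
        y = table.labels
        sub = table.select_columns([k == "numeric" for k in table.column_kinds])
        model = fit_nb(sub, NBConfig(var_floor=1e-12))
        ref = sklearn_nb.GaussianNB(var_smoothing=0.0).fit(X, y)
        assert np.allclose(
            predict_proba(model, sub), ref.predict_proba(X), atol=1e-8
        )
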