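"""BTR scoring, decision rule, threshold optimisation and regression scaling."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from btrlearn import (AbundanceMatrix, SampleTarget, canonicalize,
                      fit_model_threshold, fit_regression_scaling, make_model,
                      model_from_dict, model_to_dict, optimize_threshold,
                      predict, score_samples)
from btrlearn.data_io import ValidationError
from btrlearn.models import BTRModel, DegenerateFitError, ModelError


def _matrix(values, scale="relative"):
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    return AbundanceMatrix(values, [f"f{i}" for i in range(p)],
                           [f"s{j}" for j in range(n)], scale, validate=False)


class TestScoreSamples:
    def test_ter_signed_sum(self):
        m = _matrix([[0.10], [0.05], [0.08], [0.77]])
        mdl = make_model("ter", (0, 1, 2), (1, 1, -1), m)
        assert score_samples(mdl, m)[0] == pytest.approx(0.07)

    def test_ratio_sum_over_sum(self):
        m = _matrix([[0.4], [0.1], [0.1], [0.4]])
        mdl = make_model("ratio", (0, 1, 2), (1, -1, -1), m)
        assert score_samples(mdl, m)[0] == pytest.approx(2.0)

    def test_bin_cumulative_abundance_against_fitted_cut(self):
        # two-species signature summing to 8% of the community, compared to
        # a fitted cut of 9.7%: below the cut lands on the healthy side
        m = _matrix([[0.05], [0.03], [0.92]])
        mdl = dataclasses.replace(
            make_model("bin", (0, 1), (1, 1), m),
            threshold=0.097, direction="score_less",
            positive_label="healthy", negative_label="cirrhosis")
        assert score_samples(mdl, m)[0] == pytest.approx(0.08)
        assert predict(mdl, m)[0] == "healthy"

    def test_ratio_sentinels(self):
        m = _matrix([[0.5, 0.0], [0.0, 0.0], [0.5, 1.0]])
        mdl = make_model("ratio", (0, 1), (1, -1), m)
        scores = score_samples(mdl, m)
        assert scores[0] == np.inf  # x/0 with x > 0
        assert scores[1] == 0.0     # 0/0

    def test_index_out_of_range(self):
        m = _matrix([[1.0], [2.0]])
        mdl = BTRModel("bin", (5,), (1,), data_scale="relative")
        with pytest.raises((ModelError, IndexError)):
            score_samples(mdl, m)

    def test_scale_mismatch_rejected(self):
        m = _matrix([[1.0], [2.0]], scale="log")
        mdl = make_model("bin", (0,), (1,), _matrix([[1.0], [2.0]]))
        with pytest.raises(ModelError):
            score_samples(mdl, m)


class TestPredict:
    def _ratio_model(self, m, theta):
        return dataclasses.replace(
            make_model("ratio", (0, 1, 2), (1, -1, -1), m),
            threshold=theta, direction="score_greater",
            positive_label="healthy", negative_label="cirrhosis")

    def test_ratio_factor_rule(self):
        # one species 82x more abundant than the denominator pair, against a
        # fitted ratio factor theta = 81: lands on the positive (healthy) side
        m = _matrix([[0.82], [0.005], [0.005], [0.17]])
        mdl = self._ratio_model(m, 81.0)
        assert predict(mdl, m)[0] == "healthy"

    def test_tie_goes_to_non_positive(self):
        m = _matrix([[0.81], [0.005], [0.005], [0.18]])
        mdl = self._ratio_model(m, 81.0)
        assert score_samples(mdl, m)[0] == pytest.approx(81.0)
        assert predict(mdl, m)[0] == "cirrhosis"

    def test_infinite_score_is_positive_under_greater(self):
        m = _matrix([[0.8], [0.0], [0.0], [0.2]])
        mdl = self._ratio_model(m, 81.0)
        assert predict(mdl, m)[0] == "healthy"

    def test_unset_class_map_error(self):
        m = _matrix([[1.0]])
        mdl = dataclasses.replace(make_model("bin", (0,), (1,), m), threshold=0.5)
        with pytest.raises(ModelError):
            predict(mdl, m)


class TestOptimizeThreshold:
    def test_separable(self):
        thr, direction, err = optimize_threshold(
            [0.1, 0.2, 0.8, 0.9], [False, False, True, True])
        assert thr == pytest.approx(0.5)
        assert direction == "score_greater"
        assert err == 0

    def test_interleaved_min_error_one(self, threshold_oracle):
        scores = [0.1, 0.2, 0.3, 0.4]
        y = [False, True, True, False]
        _, _, err = optimize_threshold(scores, y)
        assert err == 1 == threshold_oracle(scores, y)

    def test_all_identical_scores(self):
        thr, _, err = optimize_threshold([0.3] * 6,
                                         [True, True, False, False, False, False])
        assert err == 2  # min class count
        assert np.isinf(thr)

    def test_single_class_error(self):
        with pytest.raises(ValidationError):
            optimize_threshold([0.1, 0.2], [True, True])

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force(self, seed):
        gen = np.random.default_rng(seed)
        n = int(gen.integers(2, 50))
        scores = np.round(gen.random(n), 2)  # many ties
        y = gen.random(n) < 0.5
        if y.all() or not y.any():
            y[0] = not y[0]
        from conftest import brute_force_threshold

        _, _, err = optimize_threshold(scores, y)
        assert err == brute_force_threshold(scores, y)


class TestFitModelThreshold:
    def test_separable_bin_is_perfect(self, separable_dataset):
        m, y = separable_dataset
        mdl = fit_model_threshold(make_model("bin", (0,), (1,), m), m, y)
        assert mdl.fitness == 1.0
        assert (predict(mdl, m) == np.asarray(y.values, dtype=object)).all()

    def test_ratio_cut_is_theta(self, small_dataset):
        m, y = small_dataset
        mdl = make_model("ratio", (0, 1, 3), (1, -1, -1), m)
        fitted = fit_model_threshold(mdl, m, y)
        thr, direction, _ = optimize_threshold(score_samples(mdl, m),
                                               y.positive_mask())
        assert fitted.threshold == thr
        assert fitted.direction == direction

    def test_refit_is_stable(self, small_dataset):
        m, y = small_dataset
        mdl = fit_model_threshold(make_model("ter", (0, 2, 5), (1, 1, -1), m), m, y)
        again = fit_model_threshold(mdl, m, y)
        assert again.threshold == mdl.threshold
        assert again.fitness == mdl.fitness

    def test_canonical_flip_same_decision(self, small_dataset):
        """A ter model and its global sign flip yield identical predictions
        once each is refit (the direction flag absorbs the flip)."""
        m, y = small_dataset
        a = fit_model_threshold(make_model("ter", (1, 4, 7), (-1, 1, -1), m), m, y)
        b = fit_model_threshold(canonicalize(a), m, y)
        np.testing.assert_array_equal(predict(a, m), predict(b, m))
        assert b.coefficients[0] == 1


class TestInvariances:
    def test_ratio_scale_invariance_power_of_two(self, small_dataset, rng):
        """Per-sample rescaling by powers of two (exact in binary floats)
        leaves ratio scores and predictions bit-identical."""
        m, y = small_dataset
        mdl = fit_model_threshold(make_model("ratio", (0, 2, 4), (1, 1, -1), m),
                                  m, y)
        c = 2.0 ** rng.integers(-3, 4, size=m.n_samples)
        scaled = AbundanceMatrix(m.values * c, list(m.feature_ids),
                                 list(m.sample_ids), m.scale, validate=False)
        np.testing.assert_array_equal(score_samples(mdl, m),
                                      score_samples(mdl, scaled))
        np.testing.assert_array_equal(predict(mdl, m), predict(mdl, scaled))

    def test_ratio_scale_invariance_arbitrary_constants(self, small_dataset, rng):
        m, y = small_dataset
        mdl = fit_model_threshold(make_model("ratio", (1, 3, 5), (1, -1, -1), m),
                                  m, y)
        c = rng.uniform(0.1, 10.0, size=m.n_samples)
        scaled = AbundanceMatrix(m.values * c, list(m.feature_ids),
                                 list(m.sample_ids), m.scale, validate=False)
        np.testing.assert_allclose(score_samples(mdl, m),
                                   score_samples(mdl, scaled), rtol=1e-12)
        np.testing.assert_array_equal(predict(mdl, m), predict(mdl, scaled))

    def test_bin_scores_scale_linearly(self, small_dataset, rng):
        m, _ = small_dataset
        mdl = make_model("bin", (0, 1), (1, 1), m)
        c = 3.0
        scaled = AbundanceMatrix(m.values * c, list(m.feature_ids),
                                 list(m.sample_ids), m.scale, validate=False)
        np.testing.assert_allclose(score_samples(mdl, scaled),
                                   c * score_samples(mdl, m), rtol=1e-12)

    def test_bin_equals_full_length_dot_product(self, small_dataset):
        m, _ = small_dataset
        mdl = make_model("bin", (2, 5, 9), (1, 1, 1), m)
        w = np.zeros(m.n_features)
        w[[2, 5, 9]] = 1.0
        np.testing.assert_allclose(score_samples(mdl, m), w @ m.values)

    def test_bin_decision_monotone_in_abundance(self, small_dataset):
        m, y = small_dataset
        mdl = fit_model_threshold(make_model("bin", (0, 1, 2), (1, 1, 1), m), m, y)
        pos_before = predict(mdl, m) == mdl.positive_label
        bumped = m.values.copy()
        bumped[0] += 0.05
        m2 = AbundanceMatrix(bumped, list(m.feature_ids), list(m.sample_ids),
                             m.scale, validate=False)
        pos_after = predict(mdl, m2) == mdl.positive_label
        if mdl.direction == "score_greater":
            assert not (pos_before & ~pos_after).any()


class TestRegressionScaling:
    def test_exact_linear(self, rng):
        scores = rng.random(30)
        fit = fit_regression_scaling(scores, 2.0 * scores + 1.0, metric="r2")
        assert fit.alpha == pytest.approx(2.0)
        assert fit.beta == pytest.approx(1.0)
        assert fit.value == pytest.approx(1.0)

    def test_independent_target_has_small_spearman(self):
        gen = np.random.default_rng(42)
        scores = gen.random(100)
        y = gen.permutation(scores)  # same values, no association
        fit = fit_regression_scaling(scores, y, metric="spearman_rho")
        assert abs(fit.value) < 0.2

    def test_target_scaling_equivariance(self, rng):
        scores = rng.random(25)
        y = 1.5 * scores + 0.3 + rng.normal(0, 0.05, 25)
        f1 = fit_regression_scaling(scores, y)
        f2 = fit_regression_scaling(scores, 10.0 * y)
        assert f2.alpha == pytest.approx(10.0 * f1.alpha)
        assert f2.beta == pytest.approx(10.0 * f1.beta)

    def test_constant_scores_rejected(self):
        with pytest.raises(DegenerateFitError):
            fit_regression_scaling([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_ser_metric(self, rng):
        scores = rng.random(50)
        y = 3.0 * scores + rng.normal(0, 0.01, 50)
        fit = fit_regression_scaling(scores, y, metric="ser")
        assert 0 <= fit.value < 0.1  # near-perfect fit: tiny scaled error


class TestSerialization:
    def test_round_trip_bit_identical(self, small_dataset):
        m, y = small_dataset
        mdl = fit_model_threshold(make_model("ter", (0, 3, 8), (1, -1, 1), m), m, y)
        doc = model_to_dict(mdl)
        back = model_from_dict(doc, m)
        assert back.threshold == mdl.threshold
        assert back.feature_names == mdl.feature_names
        np.testing.assert_array_equal(predict(back, m), predict(mdl, m))

    def test_resolves_against_reordered_matrix(self, small_dataset):
        m, y = small_dataset
        mdl = fit_model_threshold(make_model("bin", (0, 1), (1, 1), m), m, y)
        perm = np.arange(m.n_features)[::-1]
        m2 = m.subset_features(perm)
        back = model_from_dict(model_to_dict(mdl), m2)
        np.testing.assert_array_equal(predict(back, m2), predict(mdl, m))

    def test_ratio_side_tags(self, small_dataset):
        m, _ = small_dataset
        doc = model_to_dict(make_model("ratio", (0, 1), (1, -1), m))
        sides = {f["name"]: f["side"] for f in doc["features"]}
        assert sides[m.feature_ids[0]] == "numerator"
        assert sides[m.feature_ids[1]] == "denominator"


class TestModelInvariants:
    @pytest.mark.parametrize("language,coefs,err", [
        ("bin", (1, -1), "coefficients"),
        ("ratio", (-1, -1), "numerator"),
        ("ter", (2, 1), "coefficients"),
    ])
    def test_invalid_coefficients(self, language, coefs, err):
        with pytest.raises(ModelError, match=err):
            BTRModel(language, (0, 1), coefs,
                     data_scale="log" if language == "terlog" else "relative")

    def test_terlog_requires_log_scale(self):
        with pytest.raises(ModelError):
            BTRModel("terlog", (0,), (1,), data_scale="relative")
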