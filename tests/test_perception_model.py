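"""Logistic perception models: prediction, fitting, threshold inversion."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from percepsim.exceptions import (
    FeatureError,
    NoThresholdError,
    PercepsimError,
)
from percepsim.perception_model import (
    PerceptionModel,
    SimilarityFeatures,
    fit,
    inverse_logit,
    load_default_model,
    logit,
    predict,
    threshold_for_probability,
)
from percepsim.synthetic_data import VoteSimConfig, simulate_votes


class TestLogit:
    def test_midpoint(self):
        assert logit(0.5) == 0.0

    def test_known_value(self):
        assert logit(0.8) == pytest.approx(math.log(4), abs=1e-12)

    def test_roundtrip(self):
        assert inverse_logit(logit(0.3)) == pytest.approx(0.3, abs=1e-12)

    def test_boundary_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            y = logit(1.0, n_total=21)
        assert y == pytest.approx(math.log((1 - 1 / 42) / (1 / 42)))

    def test_out_of_domain_rejected(self):
        with pytest.raises(FeatureError):
            logit(1.5)


class TestPredict:
    def test_logistic_midpoint_tie_is_similar(self):
        model = PerceptionModel(("tXT",), omega0=0.0, omega1=1.0)
        pred = predict(model, SimilarityFeatures(tXT=0.0))
        assert pred.y_hat == 0.0
        assert pred.p_hat == 0.5
        assert pred.label == "similar"

    def test_default_single_feature_model(self):
        model = load_default_model("default_tXT")
        pred = predict(model, SimilarityFeatures(tXT=0.73))
        # sigma(-4.860 + 8.449 * 0.73)
        assert pred.p_hat == pytest.approx(0.7871, abs=5e-4)

    def test_default_double_feature_model(self):
        model = load_default_model("default_combo")
        pred = predict(model, SimilarityFeatures(tXT=1.0, tCS=2.0))
        # sigma(-5.605 + 5.214 + 2 * 2.009) = sigma(3.627)
        assert pred.y_hat == pytest.approx(3.627, abs=1e-9)
        assert pred.p_hat == pytest.approx(0.9741, abs=5e-4)

    def test_missing_feature_rejected(self):
        model = load_default_model("default_combo")
        with pytest.raises(FeatureError, match="tCS"):
            predict(model, SimilarityFeatures(tXT=0.5))

    def test_monotone_in_positive_coefficient_features(self):
        model = load_default_model("default_combo")
        p = [
            predict(model, SimilarityFeatures(tXT=t, tCS=1.0)).p_hat
            for t in (0.1, 0.4, 0.7, 1.0)
        ]
        assert p == sorted(p)


class TestThresholds:
    def test_trivial_midpoint(self):
        model = PerceptionModel(("tXT",), omega0=0.0, omega1=1.0)
        assert threshold_for_probability(model, 0.5) == 0.0

    def test_default_model_majority_threshold(self):
        model = load_default_model("default_tXT")
        assert threshold_for_probability(model, 0.5) == pytest.approx(
            4.860 / 8.449, abs=1e-6
        )

    def test_default_model_95pct_threshold(self):
        # closed-form inversion: (ln 19 + 4.860) / 8.449
        model = load_default_model("default_tXT")
        expected = (math.log(19) + 4.860) / 8.449
        assert threshold_for_probability(model, 0.95) == pytest.approx(
            expected, abs=1e-6
        )
        assert expected == pytest.approx(0.9237, abs=5e-4)

    def test_flat_model_has_no_threshold(self):
        model = PerceptionModel(("tXT",), omega0=1.0, omega1=0.0)
        with pytest.raises(NoThresholdError):
            threshold_for_probability(model, 0.5)

    def test_two_feature_model_rejected(self):
        model = load_default_model("default_combo")
        with pytest.raises(NoThresholdError):
            threshold_for_probability(model, 0.5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        omega0=st.floats(-10, 10),
        omega1=st.floats(0.1, 20),
        p=st.floats(0.01, 0.99),
    )
    def test_inversion_roundtrip(self, omega0, omega1, p):
        model = PerceptionModel(("tCS",), omega0=omega0, omega1=omega1)
        t = threshold_for_probability(model, p)
        y = omega0 + omega1 * t
        assert inverse_logit(y) == pytest.approx(p, abs=1e-9)


class TestFit:
    def test_separated_data_stays_finite(self, vote_table):
        model = fit(vote_table, ("tXT",), fit_mode="binary_label")
        assert math.isfinite(model.omega0) and math.isfinite(model.omega1)

    def test_per_vote_recovers_generating_law(self):
        table = simulate_votes(
            VoteSimConfig(true_omega0=-4.0, true_omega1=8.0, n_pairs=500, seed=3)
        )
        model = fit(table, ("tXT",), fit_mode="per_vote")
        assert model.omega1 == pytest.approx(8.0, abs=1.0)
        assert model.omega0 == pytest.approx(-4.0, abs=0.6)

    def test_estimates_improve_with_sample_size(self):
        errors = []
        for n in (100, 1000):
            table = simulate_votes(
                VoteSimConfig(true_omega0=-4.0, true_omega1=8.0, n_pairs=n, seed=11)
            )
            model = fit(table, ("tXT",), fit_mode="per_vote")
            errors.append(abs(model.omega1 - 8.0) + abs(model.omega0 + 4.0))
        assert errors[1] < errors[0]

    def test_two_feature_fit(self):
        table = simulate_votes(
            VoteSimConfig(
                true_omega0=-5.0, true_omega1=4.0, true_omega2=2.0,
                n_pairs=800, seed=5,
            )
        )
        model = fit(table, ("tXT", "tCS"), fit_mode="per_vote")
        assert model.omega2 == pytest.approx(2.0, abs=0.6)

    def test_single_class_labels_rejected(self):
        table = simulate_votes(
            VoteSimConfig(true_omega0=10.0, true_omega1=0.5, n_pairs=50, seed=1)
        )
        with pytest.raises(PercepsimError, match="degenerate"):
            fit(table, ("tXT",), fit_mode="binary_label")

    def test_regularization_metadata_recorded(self, vote_table):
        model = fit(vote_table, ("tXT",))
        assert model.regularization["type"] == "L1"
        assert model.regularization["C"] == 1.0
        assert model.regularization["lambda"] == 1.0
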