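"""The penalized logistic scorer and the multiplicative baseline."""

import numpy as np
import pytest
from scipy.optimize import approx_fprime, minimize
from scipy.special import expit, logit

from airliner.io_genomics import AirlinerError
from airliner.model import (
    AirlinerModel,
    AirlinerResults,
    MultiplicativeScorer,
    fit,
    fit_penalized_logistic,
    penalized_logistic_objective,
)
from airliner.profiles import PositionProbabilityMatrix, build_profile
from airliner.simulate import BiasSpec, generate_window_sets
from conftest import random_windows, window


class TestPenalizedLogisticFit:
    def test_zero_features_balanced_labels_intercept_only(self):
        X = np.zeros((20, 4))
        y = np.array([1.0] * 10 + [0.0] * 10)
        params, info = fit_penalized_logistic(X, y)
        assert params == pytest.approx(np.zeros(5), abs=1e-8)
        assert info["converged"]

    def test_zero_features_intercept_is_logit_prevalence(self):
        X = np.zeros((40, 3))
        y = np.array([1.0] * 10 + [0.0] * 30)  # prevalence 0.25
        params, _ = fit_penalized_logistic(X, y)
        assert params[0] == pytest.approx(logit(0.25), abs=1e-8)
        assert params[1:] == pytest.approx(np.zeros(3), abs=1e-8)

    def test_gradient_vanishes_at_solution(self, rng):
        """Central finite differences of the penalized likelihood confirm a
        stationary point (norm <= 1e-6)."""
        X = rng.uniform(0, 1, size=(50, 5))
        y = (rng.uniform(size=50) < expit(X @ rng.normal(size=5))).astype(float)
        ridge = 0.05
        params, info = fit_penalized_logistic(X, y, ridge=ridge)
        grad = approx_fprime(
            params, penalized_logistic_objective, 1e-7, X, y, ridge
        )
        assert np.linalg.norm(grad) <= 1e-6
        assert info["grad_norm"] <= 1e-8

    def test_matches_generic_minimizer_on_small_instances(self, rng):
        """Newton solution equals an independent quasi-Newton minimizer of
        the same objective within 1e-4 on random small problems."""
        for _ in range(5):
            n = int(rng.integers(20, 61))
            p = int(rng.integers(1, 7))
            X = rng.uniform(0, 1, size=(n, p))
            y = rng.integers(0, 2, size=n).astype(float)
            ridge = float(rng.uniform(0.01, 0.5))
            params, _ = fit_penalized_logistic(X, y, ridge=ridge)
            ref = minimize(
                penalized_logistic_objective,
                np.zeros(p + 1),
                args=(X, y, ridge),
                method="BFGS",
                options={"gtol": 1e-10, "maxiter": 2000},
            )
            assert np.max(np.abs(params - ref.x)) < 1e-4

    def test_determinism_bit_identical(self, rng):
        X = rng.uniform(size=(30, 4))
        y = rng.integers(0, 2, size=30).astype(float)
        p1, _ = fit_penalized_logistic(X, y)
        p2, _ = fit_penalized_logistic(X, y)
        assert np.array_equal(p1, p2)

    def test_separable_data_without_ridge_warns_at_cap(self):
        X = np.linspace(0, 1, 12).reshape(-1, 1)
        y = (X[:, 0] > 0.5).astype(float)
        with pytest.warns(UserWarning, match="separable|iteration cap"):
            _, info = fit_penalized_logistic(X, y, ridge=0.0, maxiter=5)
        assert not info["converged"]

    def test_ridge_shrinks_coefficient_norm_monotonically(self, rng):
        X = rng.uniform(size=(80, 4))
        y = (rng.uniform(size=80) < expit(X @ np.array([2.0, -1.0, 0.5, 1.5]))).astype(float)
        norms = []
        for lam in [1e-4, 1e-2, 1e-1, 1.0, 10.0]:
            params, _ = fit_penalized_logistic(X, y, ridge=lam)
            norms.append(np.linalg.norm(params[1:]))
        assert norms == sorted(norms, reverse=True)


def toy_results(beta0=0.0, beta=None, beta_prime=None, radius=1):
    width = 2 * radius + 1
    uniform = np.full((4, width), 0.25)
    ppm = PositionProbabilityMatrix(radius, uniform, 1, 1.0)
    return AirlinerResults(
        beta0=beta0,
        beta=np.zeros(width) if beta is None else np.asarray(beta, float),
        beta_prime=np.zeros(width) if beta_prime is None else np.asarray(beta_prime, float),
        radius=radius,
        ridge=1e-3,
        ppm_edited=ppm,
        ppm_unedited=ppm,
    )


class TestPrediction:
    def test_zero_model_scores_one_half_everywhere(self):
        res = toy_results()
        assert res.predict_probability(window("CAG")) == pytest.approx(0.5)

    def test_large_intercept_saturates(self):
        res = toy_results(beta0=30.0)
        assert res.predict_probability(window("CAG")) > 1 - 1e-9

    def test_hand_computed_linear_predictor(self):
        """Probability equals sigma(beta0 + sum beta*P - sum beta'*P')
        computed by hand on a 3-nt model with printed coefficients."""
        p = np.array(
            [[0.1, 0.7, 0.25], [0.2, 0.1, 0.25], [0.3, 0.1, 0.25], [0.4, 0.1, 0.25]]
        )
        q = np.array(
            [[0.4, 0.55, 0.1], [0.3, 0.15, 0.2], [0.2, 0.15, 0.3], [0.1, 0.15, 0.4]]
        )
        res = AirlinerResults(
            beta0=0.3,
            beta=np.array([1.0, -2.0, 0.5]),
            beta_prime=np.array([0.7, 0.1, -0.4]),
            radius=1,
            ridge=0.0,
            ppm_edited=PositionProbabilityMatrix(1, p, 1, 0.0),
            ppm_unedited=PositionProbabilityMatrix(1, q, 1, 0.0),
        )
        # window CAG: P-lookups 0.2, 0.7, 0.25; P'-lookups 0.3, 0.55, 0.3
        eta = 0.3 + (1.0 * 0.2 + -2.0 * 0.7 + 0.5 * 0.25) - (0.7 * 0.3 + 0.1 * 0.55 + -0.4 * 0.3)
        assert res.predict_probability(window("CAG")) == pytest.approx(
            1 / (1 + np.exp(-eta)), abs=1e-12
        )

    def test_strict_decision_rule_at_one_half(self):
        res = toy_results()  # probability exactly 0.5
        assert res.classify(window("CAG")) == "unedited"
        assert toy_results(beta0=0.05).classify(window("CAG")) == "edited"

    def test_custom_threshold(self):
        res = toy_results(beta0=logit(0.7))
        assert res.predict_probability(window("CAG")) == pytest.approx(0.7)
        assert res.classify(window("CAG"), threshold=0.9) == "unedited"

    def test_radius_mismatch_rejected(self):
        res = toy_results(radius=1)
        with pytest.raises(AirlinerError, match="radius"):
            res.predict_probability(window("CCACC"))


class TestAirlinerModelFit:
    def test_fit_builds_profiles_and_converges(self, rng):
        pos = random_windows(rng, 40, radius=2, label="edited")
        neg = random_windows(rng, 40, radius=2, label="unedited")
        res = AirlinerModel(pos, neg).fit()
        assert res.fit_info["converged"]
        assert res.beta.shape == (5,) and res.beta_prime.shape == (5,)
        assert res.ppm_edited.n_sequences == 40
        assert res.bse is not None and np.all(res.bse >= 0)

    def test_fits_are_deterministic(self, rng):
        pos = random_windows(rng, 30, radius=2, label="edited")
        neg = random_windows(rng, 30, radius=2, label="unedited")
        r1 = AirlinerModel(pos, neg).fit()
        r2 = AirlinerModel(pos, neg).fit()
        assert np.array_equal(r1.params, r2.params)

    def test_strong_positional_separation_is_learned(self):
        """Disjoint-support class profiles give near-perfect training
        accuracy; identical profiles stay near chance."""
        spec = BiasSpec.separated(radius=4, n_pos=250, n_neg=250, seed=7)
        pos, neg = generate_window_sets(spec)
        res = fit(pos, neg)
        calls = [res.classify(w) for w in pos] + [res.classify(w) for w in neg]
        truth = ["edited"] * 250 + ["unedited"] * 250
        acc = np.mean([c == t for c, t in zip(calls, truth)])
        assert acc >= 0.95

    def test_empty_class_rejected(self, rng):
        pos = random_windows(rng, 5, radius=2, label="edited")
        with pytest.raises(AirlinerError):
            AirlinerModel(pos, [])

    def test_mixed_radius_rejected(self, rng):
        pos = random_windows(rng, 5, radius=2, label="edited")
        neg = random_windows(rng, 5, radius=3, label="unedited")
        with pytest.raises(AirlinerError, match="radii"):
            AirlinerModel(pos, neg)

    def test_json_round_trip_preserves_predictions(self, rng, tmp_path):
        pos = random_windows(rng, 25, radius=2, label="edited")
        neg = random_windows(rng, 25, radius=2, label="unedited")
        res = AirlinerModel(pos, neg).fit()
        path = tmp_path / "model.json"
        res.to_json(path)
        back = AirlinerResults.from_json(path)
        w = window("GTAGT")
        assert back.predict_probability(w) == pytest.approx(
            res.predict_probability(w), abs=1e-12
        )

    def test_summary_reports_coefficients(self, rng):
        pos = random_windows(rng, 20, radius=1, label="edited")
        neg = random_windows(rng, 20, radius=1, label="unedited")
        text = AirlinerModel(pos, neg).fit().summary()
        assert "beta0" in text and "beta'[3]" in text and "ridge" in text


class TestMultiplicativeScorer:
    def test_identity_multipliers_return_base_rate(self):
        scorer = MultiplicativeScorer({-1: dict.fromkeys("ACGT", 1.0)}, base_rate=12.5)
        assert scorer.score(window("CAG")) == pytest.approx(12.5)

    def test_nonpositive_multiplier_rejected_at_load(self):
        with pytest.raises(AirlinerError, match="> 0"):
            MultiplicativeScorer({-1: {"A": 0.0, "C": 1, "G": 1, "T": 1}})

    def test_offset_zero_rejected(self):
        with pytest.raises(AirlinerError, match="offset 0"):
            MultiplicativeScorer({0: dict.fromkeys("ACGT", 1.0)})

    def test_hand_product(self):
        # 5' T doubles, 3' G triples: window TAG scores 5 * 2 * 3 = 30
        scorer = MultiplicativeScorer(
            {
                -1: {"T": 2.0, "A": 1.0, "C": 1.0, "G": 1.0},
                +1: {"G": 3.0, "A": 1.0, "C": 1.0, "T": 1.0},
            },
            base_rate=5.0,
        )
        assert scorer.score(window("TAG")) == pytest.approx(30.0)
        assert scorer.score(window("CAC")) == pytest.approx(5.0)

    def test_missing_coefficient_is_configuration_error(self):
        scorer = MultiplicativeScorer({-1: {"T": 2.0}}, base_rate=5.0)
        with pytest.raises(AirlinerError, match="no multiplier"):
            scorer.score(window("CAG"))

    def test_default_threshold_is_9_6_percent_strict(self):
        scorer = MultiplicativeScorer({-1: dict.fromkeys("ACGT", 1.0)}, base_rate=9.6)
        assert scorer.threshold_percent == 9.6
        assert scorer.classify(window("CAG")) == "unedited"  # exactly 9.6 is not >
        above = MultiplicativeScorer({-1: dict.fromkeys("ACGT", 1.0)}, base_rate=9.61)
        assert above.classify(window("CAG")) == "edited"

    def test_tsv_round_trip(self, tmp_path):
        path = tmp_path / "coef.tsv"
        rows = ["# offset\tnuc\tmult"]
        for nuc, mult in zip("ACGT", [1.0, 0.5, 2.0, 1.5]):
            rows.append(f"-1\t{nuc}\t{mult}")
            rows.append(f"1\t{nuc}\t{1.0}")
        path.write_text("\n".join(rows) + "\n")
        scorer = MultiplicativeScorer.from_tsv(path, base_rate=10.0)
        assert scorer.score(window("GAG")) == pytest.approx(20.0)
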