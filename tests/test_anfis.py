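"""Takagi-Sugeno ANFIS unit: membership layers, forward pass, hybrid fit."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cascadefis.anfis import (
    Anfis,
    AnfisModel,
    Rule,
    TrainConfig,
    TriangularMF,
    ZeroFiringError,
    build_grid_model,
    fit_consequents_lse,
    firing_strengths,
    forward,
    forward_batch,
    mf_eval,
    normalize_firing,
    train,
)


def brute_force_forward(x, model):
    """Independent rule-loop evaluator of the weighted Takagi-Sugeno sum."""
    w = [
        math.prod(mf_eval(x[i], mf) for i, mf in enumerate(r.premise))
        for r in model.rules
    ]
    s = sum(w)
    return sum(
        wi / s * (float(np.dot(r.consequent[:-1], x)) + r.consequent[-1])
        for wi, r in zip(w, model.rules)
    )


def random_model(rng, m):
    """Random small 2-input grid model with jittered MFs and consequents."""
    ranges = np.array([[-1.0, 1.0], [-2.0, 2.0]])
    model = build_grid_model(ranges, m)
    rules = []
    for rule in model.rules:
        premise = tuple(
            TriangularMF(*sorted(np.array([mf.a, mf.b, mf.c])
                                 + rng.normal(0, 0.05, 3)))
            for mf in rule.premise
        )
        rules.append(Rule(premise=premise, consequent=rng.normal(0, 2, 3)))
    model.rules = rules
    return model


class TestTriangularMF:
    @pytest.mark.parametrize("x,expected", [
        (1.0, 1.0),     # peak
        (-1.0, 0.0),    # outside support
        (0.5, 0.5),     # mid-ramp
        (0.0, 0.0),     # left foot
        (2.0, 0.0),     # right foot
    ])
    def test_ramp_values(self, x, expected):
        assert mf_eval(x, TriangularMF(0, 1, 2)) == expected

    def test_degenerate_plateaus_evaluate_as_one_at_shared_point(self):
        assert mf_eval(0.0, TriangularMF(0, 0, 1)) == 1.0
        assert mf_eval(1.0, TriangularMF(0, 1, 1)) == 1.0
        # outside the support still zero
        assert mf_eval(-0.1, TriangularMF(0, 0, 1)) == 0.0
        assert mf_eval(1.1, TriangularMF(0, 1, 1)) == 0.0

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            TriangularMF(1, 0, 2)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            mf_eval(float("nan"), TriangularMF(0, 1, 2))

    @settings(max_examples=200, derandomize=True)
    @given(
        x=st.floats(-10, 10),
        abc=st.tuples(st.floats(-5, 5), st.floats(-5, 5), st.floats(-5, 5)),
    )
    def test_membership_always_in_unit_interval(self, x, abc):
        mf = TriangularMF(*sorted(abc))
        assert 0.0 <= mf_eval(x, mf) <= 1.0


class TestFiringLayers:
    def test_product_of_ones(self):
        model = build_grid_model([[0, 1], [0, 1]], 2)
        w = firing_strengths([0.0, 0.0], model)
        # the rule whose premises both peak at 0 fires fully
        assert w.max() == 1.0
        assert np.all((w >= 0) & (w <= 1))

    def test_hand_computed_product(self):
        # memberships 0.4 and 0.5 for one rule -> w = 0.2
        mfs = (TriangularMF(0, 1, 2), TriangularMF(0, 2, 4))
        rule = Rule(premise=mfs, consequent=np.zeros(3))
        model = AnfisModel(arity=2, mfs_per_input=1, rules=[rule],
                           input_ranges=[[0, 2], [0, 4]])
        w = firing_strengths([0.4, 1.0], model)
        assert w[0] == pytest.approx(0.4 * 0.5, abs=1e-12)

    def test_annihilating_zero(self):
        model = build_grid_model([[0, 1], [0, 1]], 2)
        w = firing_strengths([0.0, 1.0], model)
        assert np.any(w == 0)

    def test_arity_mismatch(self):
        model = build_grid_model([[0, 1], [0, 1]], 2)
        with pytest.raises(ValueError):
            firing_strengths([0.5], model)

    @pytest.mark.parametrize("w,expected", [
        ([1, 1, 2], [0.25, 0.25, 0.5]),
        ([5], [1.0]),
    ])
    def test_normalization(self, w, expected):
        assert np.allclose(normalize_firing(w), expected, atol=1e-12)

    def test_zero_total_firing_is_an_error(self):
        with pytest.raises(ZeroFiringError, match="zero total firing"):
            normalize_firing([0.0, 0.0])

    def test_normalized_sum_is_one(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            w = rng.uniform(0, 1, rng.integers(1, 9))
            w[0] += 1e-9  # keep the total positive
            assert normalize_firing(w).sum() == pytest.approx(1.0, abs=1e-9)


class TestForward:
    def test_constant_consequents_give_the_constant(self):
        model = build_grid_model([[0, 1], [0, 1]], 2)
        for rule in model.rules:
            rule.consequent = np.array([0.0, 0.0, 5.0])
        for x in ([0.2, 0.9], [0.0, 0.0], [1.0, 0.5]):
            assert forward(x, model) == pytest.approx(5.0, abs=1e-12)

    def test_single_rule_passes_through_first_input(self):
        rule = Rule(
            premise=(TriangularMF(-10, 0, 10), TriangularMF(-10, 0, 10)),
            consequent=np.array([1.0, 0.0, 0.0]),
        )
        model = AnfisModel(arity=2, mfs_per_input=1, rules=[rule],
                           input_ranges=[[-10, 10], [-10, 10]])
        assert forward([3.0, -7.0], model) == pytest.approx(3.0, abs=1e-12)

    def test_forward_matches_brute_force_oracle_on_random_models(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for trial in range(120):
            model = random_model(rng, m=2 if trial % 2 == 0 else 3)
            x = rng.uniform([-0.9, -1.8], [0.9, 1.8])
            try:
                got = forward(x, model)
            except ZeroFiringError:
                continue
            worst = max(worst, abs(got - brute_force_forward(x, model)))
        assert worst <= 1e-12

    def test_batch_forward_agrees_with_scalar_forward(self):
        rng = np.random.default_rng(5)
        model = random_model(rng, 2)
        X = rng.uniform([-0.9, -1.8], [0.9, 1.8], (30, 2))
        batch = forward_batch(X, model, on_zero_firing="clamp")
        for i in range(len(X)):
            try:
                assert batch[i] == pytest.approx(forward(X[i], model),
                                                 abs=1e-12)
            except ZeroFiringError:
                pass

    def test_out_of_range_input_errors_then_clamps(self):
        model = build_grid_model([[0, 1], [0, 1]], 2)
        for rule in model.rules:
            rule.consequent = np.array([0.0, 0.0, 2.0])
        X = np.array([[5.0, 5.0]])
        with pytest.raises(ZeroFiringError):
            forward_batch(X, model, on_zero_firing="error")
        assert forward_batch(X, model, on_zero_firing="clamp")[0] == \
            pytest.approx(2.0)


class TestConsequentLSE:
    def test_linear_target_recovered_exactly(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, (60, 2))
        y = 2 * X[:, 0] + 3 * X[:, 1] + 1
        model = build_grid_model(
            np.column_stack([X.min(0), X.max(0)]), 2)
        fitted = fit_consequents_lse(X, y, model, ridge=1e-8)
        pred = forward_batch(X, fitted, on_zero_firing="clamp")
        assert np.sqrt(np.mean((pred - y) ** 2)) <= 1e-6

    def test_constant_target_reproduced(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, (30, 2))
        y = np.full(30, 4.2)
        model = build_grid_model(np.column_stack([X.min(0), X.max(0)]), 2)
        fitted = fit_consequents_lse(X, y, model, ridge=1e-10)
        pred = forward_batch(X, fitted, on_zero_firing="clamp")
        assert np.allclose(pred, 4.2, atol=1e-6)

    def test_duplicated_rows_give_identical_coefficients(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(-1, 1, (25, 2))
        y = np.sin(X[:, 0]) + X[:, 1] ** 2
        model = build_grid_model(np.column_stack([X.min(0), X.max(0)]), 2)
        f1 = fit_consequents_lse(X, y, model)
        f2 = fit_consequents_lse(np.vstack([X, X]), np.concatenate([y, y]),
                                 model)
        for r1, r2 in zip(f1.rules, f2.rules):
            assert np.allclose(r1.consequent, r2.consequent, atol=1e-8)

    def test_rank_deficient_design_without_ridge_raises(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(-1, 1, (40, 2))
        y = X[:, 0]
        model = build_grid_model(np.column_stack([X.min(0), X.max(0)]), 2)
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            fit_consequents_lse(X, y, model, ridge=0.0)

    def test_lse_step_never_increases_training_rmse(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            X = rng.uniform(-1, 1, (50, 2))
            y = rng.normal(0, 1, 50)
            model = random_model(rng, 2)
            before = forward_batch(X, model, on_zero_firing="clamp")
            rmse_before = np.sqrt(np.mean((before - y) ** 2))
            fitted = fit_consequents_lse(X, y, model, ridge=1e-12)
            after = forward_batch(X, fitted, on_zero_firing="clamp")
            rmse_after = np.sqrt(np.mean((after - y) ** 2))
            assert rmse_after <= rmse_before + 1e-9


class TestHybridTraining:
    def test_noiseless_linear_target_solved_at_epoch_one(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, (60, 2))
        y = 2 * X[:, 0] + 3 * X[:, 1] + 1
        model = build_grid_model(np.column_stack([X.min(0), X.max(0)]), 2)
        _, trace = train(X, y, model, TrainConfig(epochs=1))
        assert trace[0] <= 1e-6

    def test_constant_target_gives_zero_trace(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, (30, 2))
        y = np.zeros(30)
        model = build_grid_model(np.column_stack([X.min(0), X.max(0)]), 2)
        _, trace = train(X, y, model, TrainConfig(epochs=3))
        assert np.allclose(trace, 0.0, atol=1e-9)

    def test_training_is_deterministic(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(-1, 1, (40, 2))
        y = np.tanh(X[:, 0] * X[:, 1])
        model = build_grid_model(np.column_stack([X.min(0), X.max(0)]), 2)
        _, t1 = train(X, y, model, TrainConfig(epochs=4, seed=7))
        _, t2 = train(X, y, model, TrainConfig(epochs=4, seed=7))
        assert np.array_equal(t1, t2)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(premise_lr=-0.1)


class TestModelContainer:
    def test_grid_partition_rule_count(self):
        model = build_grid_model([[0, 1], [0, 1]], 3)
        assert model.n_rules == 9

    def test_wrong_rule_count_rejected(self):
        model = build_grid_model([[0, 1], [0, 1]], 2)
        with pytest.raises(ValueError):
            AnfisModel(arity=2, mfs_per_input=2, rules=model.rules[:3],
                       input_ranges=[[0, 1], [0, 1]])

    def test_json_round_trip_is_exact(self):
        rng = np.random.default_rng(9)
        model = random_model(rng, 2)
        clone = AnfisModel.from_json(model.to_json())
        X = rng.uniform(-1, 1, (20, 2))
        a = forward_batch(X, model, on_zero_firing="clamp")
        b = forward_batch(X, clone, on_zero_firing="clamp")
        assert np.array_equal(a, b)
        assert json.loads(model.to_json()) == json.loads(clone.to_json())


class TestStatsmodelsSurface:
    def test_fit_predict_and_summary(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, (80, 2))
        y = X[:, 0] - 0.5 * X[:, 1]
        res = Anfis(y, X).fit(epochs=2)
        assert res.rmse <= 1e-5
        assert np.allclose(res.predict(X), y, atol=1e-4)
        text = res.summary()
        assert "Rules" in text and "Training RMSE" in text
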