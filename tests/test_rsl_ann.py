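"""Network mechanics, SCG training, and the RSL construction procedure."""

import numpy as np
import pytest

from fibrillens.errors import ValidationError
from fibrillens.rsl_ann import (
    Architecture,
    TrainConfig,
    class_weights,
    derive_seeds,
    enumerate_alternatives,
    forward,
    init_model,
    multi_restart,
    rsl_construct,
    scg_train,
    screen_candidate,
    weighted_loss,
)
from fibrillens.rsl_ann import _loss_and_grad
from fibrillens.scg import scg_minimize


def _toy_blobs(n=120, seed=1, gap=1.2, scale=0.5):
    rng = np.random.default_rng(seed)
    X = np.r_[
        rng.normal(-gap, scale, size=(n, 2)), rng.normal(gap, scale, size=(n, 2))
    ]
    y = np.r_[np.zeros(n), np.ones(n)]
    idx = rng.permutation(2 * n)
    X, y = X[idx], y[idx]
    cut = int(0.7 * 2 * n)
    return (X[:cut], y[:cut]), (X[cut:], y[cut:])


class TestArchitecture:
    def test_layer_width_constraint(self):
        with pytest.raises(ValidationError):
            Architecture((2, 3))

    def test_depth_constraint(self):
        with pytest.raises(ValidationError):
            Architecture((4, 3, 2, 1))

    def test_parameter_count_arithmetic(self):
        # 19*2+2 weights+biases into layer 1, 2*1+1 into layer 2, 1*1+1 out
        assert Architecture((2, 1)).n_params(19) == 45

    @pytest.mark.parametrize(
        "arch,expected",
        [
            ((1,), {(2,), (1, 1)}),
            ((2, 1), {(3, 1), (2, 2), (2, 1, 1)}),
            ((6, 6, 5), {(7, 6, 5), (6, 6, 6)}),
        ],
    )
    def test_enumerate_alternatives(self, arch, expected):
        got = {a.hidden_sizes for a in enumerate_alternatives(Architecture(arch))}
        assert got == expected


class TestModel:
    def test_init_bounds_and_determinism(self):
        m1 = init_model(Architecture((4, 2)), seed=7)
        m2 = init_model(Architecture((4, 2)), seed=7)
        vec = m1.to_vector()
        assert np.all(vec >= -1.0) and np.all(vec <= 1.0)
        np.testing.assert_array_equal(vec, m2.to_vector())

    def test_zero_parameters_score_half(self):
        m = init_model(Architecture((3,)), seed=0)
        for w in m.weights:
            w[...] = 0.0
        for b in m.biases:
            b[...] = 0.0
        assert forward(m, np.zeros(19)) == pytest.approx(0.5)

    def test_hand_built_single_unit_network(self):
        # one hidden unit over one active input, evaluated by hand
        m = init_model(Architecture((1,)), seed=0, n_inputs=2)
        m.weights[0][...] = [[0.8, 0.0]]
        m.biases[0][...] = [0.1]
        m.weights[1][...] = [[-1.5]]
        m.biases[1][...] = [0.4]
        x = np.array([0.6, 123.0 * 0])
        h = 1 / (1 + np.exp(-(0.8 * 0.6 + 0.1)))
        expected = 1 / (1 + np.exp(-(-1.5 * h + 0.4)))
        assert forward(m, x) == pytest.approx(expected, abs=1e-12)

    def test_scores_strictly_inside_unit_interval(self, rng):
        m = init_model(Architecture((3, 2)), seed=3)
        s = forward(m, rng.normal(scale=50, size=(40, 19)))
        assert np.all((s > 0) & (s < 1))

    def test_wrong_feature_count_raises(self):
        m = init_model(Architecture((2,)), seed=0)
        with pytest.raises(ValidationError):
            forward(m, np.zeros(7))

    def test_analytic_gradient_matches_numeric(self, rng):
        m = init_model(Architecture((3, 2)), seed=5, n_inputs=4)
        X = rng.normal(size=(12, 4))
        y = (rng.random(12) < 0.4).astype(float)
        cw = class_weights(y)
        w = np.where(y == 1, cw[1], cw[0])
        vec = m.to_vector()
        f0, g = _loss_and_grad(m.copy(), vec, X, y, w, "cross_entropy")
        eps = 1e-6
        num = np.empty_like(g)
        for i in range(vec.size):
            vp, vm = vec.copy(), vec.copy()
            vp[i] += eps
            vm[i] -= eps
            num[i] = (
                _loss_and_grad(m.copy(), vp, X, y, w, "cross_entropy")[0]
                - _loss_and_grad(m.copy(), vm, X, y, w, "cross_entropy")[0]
            ) / (2 * eps)
        assert np.max(np.abs(g - num)) / np.max(np.abs(num)) < 1e-6


class TestLoss:
    def test_perfect_scores_vanish(self):
        y = np.array([0, 1, 1, 0])
        s = np.where(y == 1, 1 - 1e-9, 1e-9)
        assert weighted_loss(s, y) < 1e-6

    def test_inverse_prevalence_ratio(self):
        w = class_weights(np.array([1, 0, 0, 0]))
        assert w[1] / w[0] == pytest.approx(3.0)

    def test_uniform_half_scores_give_weighted_log_two(self):
        y = np.array([1, 0, 0, 0])
        # w_AF = 2, w_non = 2/3: mean weight is exactly 1
        assert weighted_loss(np.full(4, 0.5), y) == pytest.approx(np.log(2))

    def test_empty_batch_raises(self):
        with pytest.raises(ValidationError):
            weighted_loss([], [])


class TestScgTraining:
    def test_quadratic_reaches_closed_form_minimiser(self, rng):
        A = rng.normal(size=(6, 6))
        A = A @ A.T + 6 * np.eye(6)
        b = rng.normal(size=6)
        x, _, _ = scg_minimize(
            lambda v: (0.5 * v @ A @ v - b @ v, A @ v - b), np.zeros(6), max_iter=300
        )
        assert np.max(np.abs(x - np.linalg.solve(A, b))) < 1e-6

    def test_separable_toy_trains_to_perfection(self):
        train, val = _toy_blobs()
        model = init_model(Architecture((2,)), seed=1, n_inputs=2)
        res = scg_train(model, train, val, TrainConfig())
        assert res.train_curve[3] < res.train_curve[0]  # early descent
        pred = (np.asarray(forward(res.model, train[0])) >= 0.5).astype(float)
        assert np.mean(pred == train[1]) == 1.0

    def test_early_stopping_at_patience_exhaustion(self):
        # validation labels inverted: validation loss rises while training
        # improves, so the stop must come `patience` epochs after the best
        train, val = _toy_blobs()
        bad_val = (val[0], 1.0 - val[1])
        cfg = TrainConfig(patience=4, max_epochs=500)
        model = init_model(Architecture((2,)), seed=2, n_inputs=2)
        res = scg_train(model, train, bad_val, cfg)
        assert res.stop_epoch - res.best_epoch == cfg.patience
        assert res.validation_loss == min(res.validation_curve)


class TestStructuring:
    def test_screen_accepts_when_primitive_is_beatable(self):
        train, val = _toy_blobs()
        cfg = TrainConfig()
        rng = np.random.default_rng(0)
        primitive = init_model(Architecture((1,)), seed=1, n_inputs=2)
        model, trials, _ = screen_candidate(
            Architecture((2,)), primitive, np.inf, train, val, cfg, rng
        )
        assert model is not None and trials == 1
        assert model.architecture.hidden_sizes == (2,)

    def test_screen_rejects_unbeatable_primitive(self):
        train, val = _toy_blobs()
        cfg = TrainConfig(screen_trials=5)
        rng = np.random.default_rng(0)
        primitive = init_model(Architecture((1,)), seed=1, n_inputs=2)
        model, trials, _ = screen_candidate(
            Architecture((2,)), primitive, -1.0, train, val, cfg, rng
        )
        assert model is None and trials == 5

    def test_screening_reproducible_given_seed(self):
        train, val = _toy_blobs()
        cfg = TrainConfig()
        primitive = init_model(Architecture((1,)), seed=1, n_inputs=2)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            model, trials, probe = screen_candidate(
                Architecture((1, 1)), primitive, 0.05, train, val, cfg, rng
            )
            out.append((None if model is None else model.to_vector(), trials, probe))
        assert out[0][1:] == out[1][1:]
        if out[0][0] is not None:
            np.testing.assert_array_equal(out[0][0], out[1][0])


class TestRslConstruct:
    def test_separable_toy_stops_on_zero_misclassification(self):
        train, val = _toy_blobs(gap=1.6, scale=0.4)
        model, log = rsl_construct(train, val, TrainConfig(), seed=42, n_inputs=2)
        assert log.stop_reason == "zero_misclassification"
        assert sum(model.architecture.hidden_sizes) <= 2

    def test_every_intermediate_architecture_is_legal(self):
        # overlapping classes force a longer search
        train, val = _toy_blobs(gap=0.35, scale=1.0)
        cfg = TrainConfig(max_rounds=6, max_epochs=150)
        _model, log = rsl_construct(train, val, cfg, seed=3, n_inputs=2)
        assert len(log.rounds) >= 2
        for arch in log.architectures_visited():
            assert len(arch.hidden_sizes) <= 3
            assert all(b <= a for a, b in zip(arch.hidden_sizes, arch.hidden_sizes[1:]))
        # adopted primitives grow by exactly one neuron per structuring step
        prims = [r.primitive for r in log.rounds]
        for a, b in zip(prims, prims[1:]):
            assert sum(b.hidden_sizes) - sum(a.hidden_sizes) in (0, 1)

    def test_construction_deterministic_given_seed(self):
        train, val = _toy_blobs()
        m1, log1 = rsl_construct(train, val, TrainConfig(max_rounds=4), 7, n_inputs=2)
        m2, log2 = rsl_construct(train, val, TrainConfig(max_rounds=4), 7, n_inputs=2)
        np.testing.assert_array_equal(m1.to_vector(), m2.to_vector())
        assert log1.stop_reason == log2.stop_reason


class TestMultiRestart:
    def test_single_restart_equals_construct(self):
        train, val = _toy_blobs()
        cfg = TrainConfig(max_rounds=3)
        best, logs = multi_restart(train, val, cfg, n_restarts=1, seed=5, n_inputs=2)
        child = derive_seeds(5, 1)[0]
        direct, _ = rsl_construct(train, val, cfg, child, n_inputs=2)
        np.testing.assert_array_equal(best.to_vector(), direct.to_vector())

    def test_winner_has_minimal_recorded_loss(self):
        train, val = _toy_blobs(gap=0.5, scale=1.0)
        cfg = TrainConfig(max_rounds=2, max_epochs=100)
        best, logs = multi_restart(train, val, cfg, n_restarts=3, seed=1, n_inputs=2)
        losses = [log.final_validation_loss for log in logs]
        winner = [
            log.final_validation_loss
            for log in logs
            if log.final_architecture == best.architecture
        ]
        assert min(losses) in winner

    def test_derived_seeds_distinct_and_bounded(self):
        seeds = derive_seeds(123, 100)
        assert len(set(seeds)) == 100
        assert all(0 <= s < 2**31 for s in seeds)
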