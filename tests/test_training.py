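"""Loss, exact gradients, ADADELTA updates, and the fit loop."""

import numpy as np
import pytest

from mfdl.functional import Param
from mfdl.model import HeadConfig, SubnetConfig, build_model
from mfdl.training import (
    AdadeltaState,
    FitSchedule,
    LossSpec,
    TrainingData,
    adadelta_step,
    fit,
    gradients,
    loss,
    select_lambda,
)
from conftest import random_ovf


def small_model(seed=0, activation="tanh"):
    cfgs = [SubnetConfig(modality_kind="functional", embedding_width=4,
                         marker_basis=(4, 5), layer_basis=(3, 4), grid_size=30,
                         activation=activation),
            SubnetConfig(modality_kind="dense", n_features=2, embedding_width=3,
                         activation=activation)]
    return build_model(cfgs, HeadConfig(hidden_widths=(5,), output_dim=1,
                                        activation=activation), seed=seed)


def small_batch(rng, n=12):
    return [random_ovf(rng, n=n, p=10), rng.standard_normal((n, 2))]


class TestLoss:
    def test_zero_residual_zero_lambda(self):
        y = np.array([[1.0], [2.0]])
        assert loss(y, y, [], LossSpec(0.0)) == (0.0, 0.0)

    def test_printed_formula_arithmetic(self):
        y, yhat = np.array([[0.0], [2.0]]), np.array([[0.0], [0.0]])
        J, Jt = loss(y, yhat, [], LossSpec(0.0))
        assert J == Jt == 2.0  # (0 + 4) / 2

    def test_penalty_is_half_squared_norm_of_weights(self):
        y, yhat = np.array([[0.0], [2.0]]), np.array([[0.0], [0.0]])
        params = [Param("W", np.array([[2.0]]), penalized=True),
                  Param("b", np.array([9.0]), penalized=False)]
        J, Jt = loss(y, yhat, params, LossSpec(1.0))
        assert (J, Jt) == (2.0, 4.0)  # Omega = ||W||^2 / 2 = 2; bias excluded

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            loss(np.zeros((3, 1)), np.zeros((4, 1)), [], LossSpec())


class TestGradients:
    def test_zero_residual_zero_lambda_gives_zero_gradients(self, rng):
        model = small_model()
        mods = small_batch(rng)
        y = model.forward(mods)
        grads = gradients(model, mods, None, y, LossSpec(0.0))
        assert all(np.allclose(g, 0.0) for g in grads.values())

    def test_penalty_gradient_is_lambda_w(self, rng):
        model = small_model()
        mods = small_batch(rng)
        y = model.forward(mods)
        lam = 0.7
        grads = gradients(model, mods, None, y, LossSpec(lam))
        for p in model.params:
            expected = lam * p.value if p.penalized else np.zeros_like(p.value)
            assert np.allclose(grads[p.name], expected, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("activation", ["tanh", "identity", "sigmoid"])
    def test_finite_difference_check(self, seed, activation):
        """Analytic gradients of J~ match central differences on every layer
        type (functional first/hidden/output, dense subnet, dense head)."""
        rng = np.random.default_rng(100 + seed)
        model = small_model(seed=seed, activation=activation)
        mods = small_batch(rng)
        y = rng.standard_normal((12, 1))
        spec = LossSpec(0.3)
        grads = gradients(model, mods, None, y, spec)
        h = 1e-5
        checked = 0
        for p in model.params:
            for _ in range(2):
                idx = tuple(rng.integers(0, s) for s in p.value.shape)
                orig = p.value[idx]
                p.value[idx] = orig + h
                _, jp = loss(y, model.forward(mods), model.params, spec)
                p.value[idx] = orig - h
                _, jm = loss(y, model.forward(mods), model.params, spec)
                p.value[idx] = orig
                fd = (jp - jm) / (2 * h)
                an = grads[p.name][idx]
                assert abs(fd - an) <= 1e-4 * max(1.0, abs(fd)), (p.name, idx)
                checked += 1
        assert checked >= 25

    def test_nonfinite_forward_reported(self, rng):
        model = small_model()
        mods = small_batch(rng)
        model.params[0].value = model.params[0].value * np.inf
        from mfdl.training import DivergenceError

        with pytest.raises(DivergenceError):
            gradients(model, mods, None, np.zeros((12, 1)), LossSpec())


class TestAdadelta:
    def test_zero_gradient_leaves_parameters(self):
        p = Param("w", np.array([1.0, -2.0]))
        state = AdadeltaState()
        state._ensure("w", p.value)
        state.acc_grad_sq["w"][:] = 4.0
        adadelta_step(state, [p], {"w": np.zeros(2)})
        assert np.array_equal(p.value, [1.0, -2.0])
        assert np.allclose(state.acc_grad_sq["w"], 0.95 * 4.0)

    def test_first_step_matches_scalar_oracle(self):
        # fresh state, g=1: dx = -sqrt(eps)/sqrt(0.05 + eps)
        p = Param("w", np.array([0.0]))
        state = AdadeltaState(rho=0.95, eps=1e-6)
        adadelta_step(state, [p], {"w": np.array([1.0])})
        expected = -np.sqrt(1e-6) / np.sqrt(0.05 + 1e-6)
        assert p.value[0] == pytest.approx(expected, rel=1e-6)
        assert p.value[0] == pytest.approx(-4.4719e-3, rel=1e-3)

    def test_constant_gradient_step_stabilizes(self):
        # scalar recursion driven by g=1 settles to a stable step size
        p = Param("w", np.array([0.0]))
        state = AdadeltaState()
        steps = []
        prev = 0.0
        for _ in range(10_000):
            adadelta_step(state, [p], {"w": np.array([1.0])})
            steps.append(prev - p.value[0])
            prev = p.value[0]
        last = np.abs(np.array(steps[-100:]))
        assert np.abs(np.diff(last)).max() / last.mean() < 1e-3


class TestFit:
    def test_zero_epochs_returns_initial_model(self, rng):
        model = small_model(seed=4)
        before = [p.value.copy() for p in model.params]
        mods = small_batch(rng)
        _, hist = fit(model, TrainingData(modalities=mods, y=rng.standard_normal((12, 1))),
                      schedule=FitSchedule(max_epochs=0))
        assert hist.empty
        for p, b in zip(model.params, before):
            assert np.array_equal(p.value, b)

    def test_noiseless_linear_problem_is_driven_below_tolerance(self, small_genotypes, rng):
        """A target in the model span (linear effect, identity activations)
        is fitted to J < 1e-3 by the gradient-descent reference mode."""
        from mfdl.basis import make_bspline_system
        from mfdl.simdata import gen_linear_effect

        basis = make_bspline_system(5, 7)
        y = gen_linear_effect(small_genotypes, 1.3, rng.standard_normal((7, 1)), basis=basis)
        sub = SubnetConfig(modality_kind="functional", n_hidden_functional_layers=0,
                           embedding_width=7, activation="identity")
        head = HeadConfig(hidden_widths=(), output_dim=1, activation="identity")
        model = build_model([sub], head, seed=0)
        _, hist = fit(model, TrainingData(modalities=[small_genotypes], y=y),
                      LossSpec(0.0),
                      FitSchedule(max_epochs=6000, optimizer="gd", learning_rate=0.005))
        assert hist["J"].iloc[-1] < 1e-3

    def test_ridge_shrinks_weight_norm(self, rng):
        mods = small_batch(rng, n=20)
        y = rng.standard_normal((20, 1))

        def weight_norm(lam):
            model = small_model(seed=6)
            fit(model, TrainingData(modalities=mods, y=y), LossSpec(lam),
                FitSchedule(max_epochs=400))
            return np.sqrt(sum(np.sum(p.value ** 2) for p in model.params if p.penalized))

        assert weight_norm(10.0) < weight_norm(0.0)

    def test_history_is_reproducible(self, rng):
        mods = small_batch(rng, n=15)
        y = rng.standard_normal((15, 1))

        def run():
            model = small_model(seed=8)
            _, hist = fit(model, TrainingData(modalities=mods, y=y), LossSpec(0.1),
                          FitSchedule(max_epochs=100))
            return hist

        h1, h2 = run(), run()
        assert np.array_equal(h1["J_tilde"].to_numpy(), h2["J_tilde"].to_numpy())

    def test_objective_mostly_non_increasing(self, rng):
        mods = small_batch(rng, n=30)
        y = rng.standard_normal((30, 1))
        model = small_model(seed=9)
        _, hist = fit(model, TrainingData(modalities=mods, y=y), LossSpec(0.1),
                      FitSchedule(max_epochs=800))
        jt = hist["J_tilde"].to_numpy()
        increases = np.sum(np.diff(jt) > 1e-8)
        assert increases < 0.05 * len(jt)


class TestSelectLambda:
    def _factory(self):
        def factory(seed):
            return small_model(seed=seed)
        return factory

    def _data(self, rng, n=24):
        mods = small_batch(rng, n=n)
        return TrainingData(modalities=mods, y=rng.standard_normal((n, 1)))

    def test_singleton_grid(self, rng):
        lam, _ = select_lambda(self._factory(), self._data(rng), [1.0],
                               schedule=FitSchedule(max_epochs=20))
        assert lam == 1.0

    def test_choice_is_grid_member_and_argmin(self, rng):
        grid = [0.1, 1.0, 10.0]
        lam, table = select_lambda(self._factory(), self._data(rng), grid,
                                   schedule=FitSchedule(max_epochs=60))
        assert lam in grid
        best = table.loc[table["lambda"] == lam, "val_mse"].iloc[0]
        assert (best <= table["val_mse"] + 1e-12).all()

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="nonempty"):
            select_lambda(self._factory(), self._data(rng), [])
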