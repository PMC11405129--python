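"""FLM, plain NN and FNN-3HL baselines."""

import numpy as np
import pytest

from mfdl.basis import make_bspline_system
from mfdl.baselines import (
    FNN3HL,
    SingularDesignError,
    concat_pseudo_modality,
    concat_raw,
    fit_flm,
    fit_fnn3hl,
    fit_nn,
    flm_objective,
    predict_flm,
)
from mfdl.functional import dirac_design
from mfdl.model import HeadConfig, SubnetConfig, build_model
from mfdl.simdata import gen_linear_effect
from mfdl.training import FitSchedule, LossSpec, TrainingData, fit
from conftest import random_ovf


class TestFLM:
    def test_matches_normal_equations_oracle(self, rng, small_genotypes):
        basis = make_bspline_system(4, 6)
        e = rng.standard_normal((50, 2))
        y = rng.standard_normal((50, 1))
        lam = 0.7
        model = fit_flm([small_genotypes, e], None, y, bases=[basis, None],
                        ridge_lambda=lam)
        A = np.concatenate(
            [np.ones((50, 1)), dirac_design(small_genotypes, basis), e], axis=1)
        P = np.eye(A.shape[1])
        P[0, 0] = 0.0
        expected = np.linalg.solve(A.T @ A + 50 * lam / 2 * P, A.T @ y)
        assert np.allclose(model.coef, expected, atol=1e-8)

    def test_huge_ridge_shrinks_to_intercept(self, rng, small_genotypes):
        y = rng.standard_normal((50, 1)) + 3.0
        model = fit_flm([small_genotypes], None, y, ridge_lambda=1e8)
        coef = model.coef
        assert np.abs(coef[1:]).max() < 1e-4
        assert coef[0, 0] == pytest.approx(y.mean(), abs=1e-3)

    def test_noiseless_in_span_recovery(self, rng, small_genotypes):
        """Data generated by the linear effect in the fitting basis is
        recovered with test R^2 > 0.99."""
        basis = make_bspline_system(5, 7)
        C = rng.standard_normal((7, 1))
        y = gen_linear_effect(small_genotypes, 1.3, C, basis=basis)
        tr, te = np.arange(35), np.arange(35, 50)
        from mfdl.training import _subset_modalities

        model = fit_flm(_subset_modalities([small_genotypes], tr), None, y[tr],
                        bases=[basis], ridge_lambda=1e-8)
        pred = predict_flm(model, _subset_modalities([small_genotypes], te))
        ss_res = np.sum((y[te] - pred) ** 2)
        ss_tot = np.sum((y[te] - y[te].mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.99

    def test_constant_prediction_from_intercept_only(self, rng, small_genotypes):
        model = fit_flm([small_genotypes], None, rng.standard_normal((50, 1)),
                        ridge_lambda=0.5)
        model.coef[1:] = 0.0
        model.coef[0, 0] = 4.2
        assert np.allclose(predict_flm(model, [small_genotypes]), 4.2)

    def test_prediction_linearity(self, rng, small_genotypes):
        from mfdl.functional import OmicsVariantFunction

        model = fit_flm([small_genotypes], None, rng.standard_normal((50, 1)),
                        ridge_lambda=0.3)
        g = small_genotypes
        g2 = OmicsVariantFunction(rng.integers(0, 3, g.values.shape).astype(float),
                                  g.positions01)
        gsum = OmicsVariantFunction(g.values + g2.values, g.positions01)
        lhs = predict_flm(model, [gsum])
        intercept = model.coef[0, 0]
        rhs = predict_flm(model, [g]) + predict_flm(model, [g2]) - intercept
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_training_predictions_consistent_with_fit(self, rng, small_genotypes):
        y = rng.standard_normal((50, 1))
        model = fit_flm([small_genotypes], None, y, ridge_lambda=0.2)
        p1 = predict_flm(model, [small_genotypes])
        p2 = predict_flm(model, [small_genotypes])
        assert np.array_equal(p1, p2)

    def test_singular_design_message(self):
        from mfdl.functional import build_variant_function

        # two identical constant marker columns at lambda=0: rank-deficient
        vals = np.ones((10, 2))
        ovf = build_variant_function(vals, [100, 200])
        with pytest.raises(SingularDesignError, match="ridge_lambda"):
            fit_flm([ovf], None, np.ones((10, 1)), bases=[make_bspline_system(1, 4)],
                    ridge_lambda=0.0)


class TestDenseNN:
    def test_convex_case_matches_ridge_oracle(self, rng):
        """With no hidden layers the NN objective is ridge regression; the
        trained weights must agree with the closed form."""
        X = rng.standard_normal((40, 3))
        beta = np.array([[1.0], [-2.0], [0.5]])
        y = X @ beta + 0.1 * rng.standard_normal((40, 1))
        lam = 0.5
        model, _ = fit_nn(X, y, hidden_widths=(), ridge_lambda=lam,
                          schedule=FitSchedule(max_epochs=20_000, optimizer="gd",
                                               learning_rate=0.05),
                          seed=1, activation="identity")
        # ridge with unpenalized intercept: solve on centered data
        A = np.concatenate([X, np.ones((40, 1))], axis=1)
        P = np.eye(4)
        P[3, 3] = 0.0
        ref = np.linalg.solve(A.T @ A + 40 * lam / 2 * P, A.T @ y)
        W, b = model.layers[0].W.value, model.layers[0].b.value
        assert np.abs(W - ref[:3]).max() < 1e-4
        assert abs(b[0] - ref[3, 0]) < 1e-4

    def test_deterministic_per_seed(self, rng):
        X = rng.standard_normal((20, 4))
        y = rng.standard_normal((20, 1))
        m1, h1 = fit_nn(X, y, seed=3, schedule=FitSchedule(max_epochs=50))
        m2, h2 = fit_nn(X, y, seed=3, schedule=FitSchedule(max_epochs=50))
        assert np.array_equal(h1["J_tilde"], h2["J_tilde"])
        for p1, p2 in zip(m1.params, m2.params):
            assert np.array_equal(p1.value, p2.value)

    def test_output_dim_matches_phenotype(self, rng):
        X = rng.standard_normal((15, 4))
        y = rng.standard_normal((15, 3))
        model, _ = fit_nn(X, y, seed=0, schedule=FitSchedule(max_epochs=5))
        assert model.forward([X]).shape == (15, 3)


class TestFNN3HL:
    def test_exactly_three_hidden_layers(self):
        model = FNN3HL(output_dim=1)
        assert model.n_hidden_layers == 3
        assert len(model.layers) == 4  # 3 hidden + output

    def test_identity_activations_reduce_to_linear_map(self, rng, small_genotypes):
        model = FNN3HL(output_dim=1, activation="identity", seed=2)
        g = small_genotypes
        # a single functional modality keeps its own positions
        Phi = dirac_design(g, model.marker_basis)
        L1, L2, L3, L4 = model.layers
        q = L1.grid.weights
        Z = Phi @ L1.W.value @ L1.E_out.T
        Z = (Z * q) @ L2.E_in @ L2.W.value @ L2.E_out.T + (L2.E_out @ L2.b.value)
        Z = (Z * q) @ L3.E_in @ L3.W.value @ L3.E_out.T + (L3.E_out @ L3.b.value)
        expected = (Z * q) @ L4.E_in @ L4.W.value + L4.b.value
        assert np.abs(model.forward([g]) - expected).max() < 1e-10

    def test_deterministic_per_seed(self, rng, small_genotypes):
        e = rng.standard_normal((50, 1))
        y = rng.standard_normal((50, 1))
        _, h1 = fit_fnn3hl([small_genotypes, e], y, seed=5,
                           schedule=FitSchedule(max_epochs=30))
        _, h2 = fit_fnn3hl([small_genotypes, e], y, seed=5,
                           schedule=FitSchedule(max_epochs=30))
        assert np.array_equal(h1["J_tilde"], h2["J_tilde"])

    def test_pseudo_positions_are_uniform(self, rng, small_genotypes):
        e = rng.standard_normal((50, 2))
        pseudo = concat_pseudo_modality([small_genotypes, e])
        assert pseudo.values.shape == (50, 32)
        assert np.allclose(pseudo.positions01, np.linspace(0, 1, 32))


class TestLinearLimitEquivalence:
    def test_identity_mfdl_reaches_flm_ridge_objective(self, rng, small_genotypes):
        """An identity-activation MFDL with no hidden functional layers spans
        the same linear model as the FLM; trained to convergence at a matched
        small penalty its J~ lands within 5% of the closed-form optimum."""
        basis = make_bspline_system(5, 7)
        y = gen_linear_effect(small_genotypes, 1.3, rng.standard_normal((7, 1)),
                              basis=basis)
        y = y + rng.normal(0, 0.5, size=y.shape)
        lam = 1e-3
        flm = fit_flm([small_genotypes], None, y, bases=[basis], ridge_lambda=lam)
        J_flm = flm_objective(flm, [small_genotypes], None, y)

        sub = SubnetConfig(modality_kind="functional", n_hidden_functional_layers=0,
                           embedding_width=7, activation="identity")
        head = HeadConfig(hidden_widths=(), output_dim=1, activation="identity")
        model = build_model([sub], head, seed=0)
        _, hist = fit(model, TrainingData(modalities=[small_genotypes], y=y),
                      LossSpec(lam),
                      FitSchedule(max_epochs=80_000, optimizer="gd",
                                  learning_rate=0.008, convergence_tol=1e-10))
        assert hist["J_tilde"].iloc[-1] <= 1.05 * J_flm
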