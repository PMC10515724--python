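"""Trainers: ADAM update arithmetic, LM optimizer, end-to-end fits."""

import numpy as np
import pytest

import biohybrid as bh
from biohybrid.errors import ContractError
from biohybrid.training import damped_gauss_newton


class TestAdamUpdate:
    def cfg(self, **kw):
        return bh.AdamConfig(**kw)

    def test_zero_gradient_zero_moments_leaves_weights(self):
        th = np.array([1.0, -2.0])
        out, _ = bh.adam_update(th, np.zeros(2), (np.zeros(2), np.zeros(2)), 1, self.cfg())
        assert np.array_equal(out, th)

    def test_first_iteration_unit_gradient_steps_by_alpha(self):
        """Bias-corrected first step: alpha * 1/(1 + eta) ~= alpha."""
        cfg = self.cfg(alpha=0.001, eta=1e-7)
        out, _ = bh.adam_update(np.zeros(1), np.ones(1), (np.zeros(1), np.zeros(1)), 1, cfg)
        assert out[0] == pytest.approx(-0.001 / (1 + 1e-7), rel=1e-12)

    def test_step_opposes_first_moment(self):
        rng = np.random.default_rng(0)
        g = rng.normal(size=6)
        cfg = self.cfg()
        out, (m, _) = bh.adam_update(np.zeros(6), g, (np.zeros(6), np.zeros(6)), 1, cfg)
        assert np.all(np.sign(out) == -np.sign(m))

    def test_quadratic_convergence(self):
        """Deterministic ADAM on f(x) = (x-3)^2 reaches 3 within 1e-3."""
        cfg = self.cfg(alpha=0.01, iterations=2000)
        x = np.zeros(1)
        m = np.zeros(1)
        v = np.zeros(1)
        for t in range(1, 2001):
            g = 2 * (x - 3.0)
            x, (m, v) = bh.adam_update(x, g, (m, v), t, cfg)
        assert abs(x[0] - 3.0) < 1e-3

    def test_config_validation(self):
        with pytest.raises(ContractError):
            bh.AdamConfig(beta1=1.0)
        with pytest.raises(ContractError):
            bh.AdamConfig(minibatch_fraction=0.0)
        with pytest.raises(ContractError):
            bh.AdamConfig(dropout_p=1.0)


class TestDampedGaussNewton:
    def test_linear_wls_matches_normal_equations(self):
        """On residuals r = (Ax - b)/sigma the LM loop must land on the
        closed-form weighted least-squares optimum."""
        rng = np.random.default_rng(4)
        A = rng.normal(size=(20, 5))
        b = rng.normal(size=20)
        sig = rng.uniform(0.5, 2.0, 20)
        Aw = A / sig[:, None]
        bw = b / sig
        x_star = np.linalg.solve(Aw.T @ Aw, Aw.T @ bw)

        res = lambda x: Aw @ x - bw
        jac = lambda x: Aw
        x, trace = damped_gauss_newton(res, jac, np.zeros(5), max_iterations=100, ftol=0.0)
        assert np.max(np.abs(x - x_star)) / np.max(np.abs(x_star)) < 1e-8
        assert trace[-1] <= trace[0]

    def test_rosenbrock_style_nonlinear_descent(self):
        res = lambda x: np.array([10 * (x[1] - x[0] ** 2), 1 - x[0]])
        jac = lambda x: np.array([[-20 * x[0], 10.0], [-1.0, 0.0]])
        x, trace = damped_gauss_newton(res, jac, np.array([-1.2, 1.0]), max_iterations=200)
        assert np.allclose(x, [1.0, 1.0], atol=1e-6)


class TestMakeValidationSet:
    def test_vanishing_sigma_copy_is_identical(self, tiny_problem):
        """In the zero-noise limit the augmented set equals the training set
        (sigma = 0 exactly is rejected by the positive-sigma contract)."""
        import dataclasses

        ds, _ = tiny_problem
        exps = [
            dataclasses.replace(e, sigmas=np.full_like(e.sigmas, 1e-300))
            for e in ds.experiments
        ]
        zero = bh.ExperimentDataset(ds.species, exps)
        aug = bh.make_validation_set(zero, 0)
        assert np.allclose(
            aug.experiments[0].values, ds.experiments[0].values, atol=1e-290
        )

    def test_fixed_seed_reproducible(self, tiny_problem):
        ds, _ = tiny_problem
        a = bh.make_validation_set(ds, 7)
        b = bh.make_validation_set(ds, 7)
        assert np.array_equal(a.experiments[0].values, b.experiments[0].values)

    def test_noise_sd_matches_sigma_table(self, small_species, feed_stream):
        rng = np.random.default_rng(0)
        times = np.arange(5.0)
        vals = np.tile(np.array([5.0, 2.0, 1.0]), (5, 1))
        sig = np.tile(np.array([0.5, 0.2, 0.1]), (5, 1))
        exps = [
            bh.Experiment(f"e{i}", times, vals.copy(), sig.copy(),
                          vals[0], 1.0, (feed_stream,))
            for i in range(700)  # > 10^4 points
        ]
        ds = bh.ExperimentDataset(small_species, exps)
        aug = bh.make_validation_set(ds, rng)
        diffs = np.concatenate(
            [(a.values - e.values) / e.sigmas for a, e in zip(aug.experiments, ds.experiments)]
        ).ravel()
        se = 1.0 / np.sqrt(2 * diffs.size)  # SE of a unit-normal sample SD
        assert abs(diffs.std(ddof=1) - 1.0) < 3 * se
        assert abs(diffs.mean()) < 3 / np.sqrt(diffs.size)


class TestTrainAdam:
    def test_self_generated_data_reaches_near_zero_wmse(self, tiny_dataset_factory):
        """Perfect-capacity toy with zero noise: full-batch deterministic ADAM
        must approach the zero-residual optimum."""
        ds, truth = tiny_dataset_factory(seed=2, hidden=(2,), scale=20.0)
        model = bh.HybridModel(truth.species, truth.layout,
                               truth.weights.copy(), substep=0.5)
        cfg = bh.AdamConfig(alpha=0.03, iterations=2000, minibatch_fraction=1.0,
                            dropout_p=0.0, seed=4)
        run = bh.train_adam(model, ds, cfg)
        assert run.kept_train_wmse < 1e-4
        assert run.kept_iteration > 0

    def test_kept_iteration_is_trace_argmin_including_init(self, tiny_dataset_factory):
        ds, truth = tiny_dataset_factory(seed=3)
        cfg = bh.AdamConfig(alpha=0.01, iterations=30, seed=0)
        run = bh.train_adam(truth, ds, cfg)
        assert run.kept_train_wmse == pytest.approx(np.min(run.train_wmse))
        assert run.kept_train_wmse <= run.train_wmse[0]
        assert len(run.train_wmse) == 31

    def test_bit_reproducible_for_fixed_seed(self, tiny_dataset_factory):
        ds, truth = tiny_dataset_factory(seed=1)
        cfg = bh.AdamConfig(alpha=0.01, iterations=15, seed=9)
        r1 = bh.train_adam(truth, ds, cfg)
        r2 = bh.train_adam(truth, ds, cfg)
        assert np.array_equal(r1.train_wmse, r2.train_wmse)
        assert np.array_equal(r1.kept_weights.flatten(), r2.kept_weights.flatten())


class TestTrainLmm:
    def test_lm_optimizer_matches_scipy_from_same_start(self, tiny_dataset_factory):
        """Independent oracle: scipy.optimize.least_squares on the same
        weighted hybrid residual function from the same initialization must
        reach the same weighted-least-squares optimum (train_lmm itself stops
        early on validation error by design, so the raw optimizer is compared)."""
        from scipy.optimize import least_squares

        from biohybrid.gradients import residual_jacobian
        from biohybrid.training import _residuals_only

        ds, truth = tiny_dataset_factory(seed=4, hidden=(), scale=5.0, n_times=8)
        rng = np.random.default_rng(99)
        noisy_vals = [
            e.values + rng.normal(0.0, 1.0, e.values.shape) * e.sigmas
            for e in ds.experiments
        ]
        ds = ds.with_values(noisy_vals)  # nonzero-residual optimum
        model = bh.HybridModel(truth.species, truth.layout, truth.weights.copy())
        th0 = bh.init_weights(model.layout, np.random.default_rng(0)).flatten()

        x_lm, trace = damped_gauss_newton(
            lambda th: _residuals_only(model, ds, th, None),
            lambda th: residual_jacobian(model, ds, weights=th)[1],
            th0, max_iterations=200, ftol=1e-15,
        )
        sol = least_squares(
            lambda th: _residuals_only(model, ds, th, None), th0, method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        sse_lm = trace[-1]
        sse_scipy = 2 * sol.cost
        assert sse_lm <= sse_scipy * (1 + 1e-3)  # at least as good ...
        assert sse_lm == pytest.approx(sse_scipy, rel=1e-3)  # ... and same optimum

    def test_perfect_capacity_zero_noise_fit(self, tiny_dataset_factory):
        ds, truth = tiny_dataset_factory(seed=8, hidden=(2,), scale=20.0)
        model = bh.HybridModel(truth.species, truth.layout, truth.weights.copy())
        cfg = bh.LmmConfig(max_iterations=80, restarts=3, patience=40, seed=1)
        run = bh.train_lmm(model, ds, cfg)
        assert float(np.min(run.train_wmse)) < 1e-6

    def test_best_of_restarts_at_least_as_good_as_each(self, tiny_dataset_factory):
        ds, truth = tiny_dataset_factory(seed=5)
        cfg = bh.LmmConfig(max_iterations=10, restarts=3, patience=5, seed=2)
        run = bh.train_lmm(truth, ds, cfg)
        vals = [s["best_val_wmse"] for s in run.info["restarts"] if s["status"] == "ok"]
        kept_val = float(run.val_wmse[run.kept_iteration])
        assert kept_val == pytest.approx(min(vals))

    def test_kept_weights_minimize_validation_trace(self, tiny_dataset_factory):
        ds, truth = tiny_dataset_factory(seed=6)
        cfg = bh.LmmConfig(max_iterations=15, restarts=1, patience=6, seed=3)
        run = bh.train_lmm(truth, ds, cfg)
        assert run.val_wmse is not None
        assert run.kept_iteration == int(np.argmin(run.val_wmse))

    def test_bit_reproducible_for_fixed_seed(self, tiny_dataset_factory):
        ds, truth = tiny_dataset_factory(seed=7)
        cfg = bh.LmmConfig(max_iterations=8, restarts=2, patience=4, seed=11)
        r1 = bh.train_lmm(truth, ds, cfg)
        r2 = bh.train_lmm(truth, ds, cfg)
        assert np.array_equal(r1.train_wmse, r2.train_wmse)
        assert np.array_equal(r1.kept_weights.flatten(), r2.kept_weights.flatten())
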