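import numpy as np
import pandas as pd
import pytest

from ropbo.errors import SchemaError, ValidationError
from ropbo.surrogate import (
    GPConfig,
    cross_validate,
    fit,
    predict,
    predict_arrays,
    refit_fixed,
    split_sizes,
)


def matern52(a, b, lengthscales, signal_var):
    """Hand-written Matern-5/2 ARD kernel, independent of sklearn."""
    a = np.atleast_2d(a) / lengthscales
    b = np.atleast_2d(b) / lengthscales
    d = np.sqrt(
        np.maximum(
            ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1), 0.0
        )
    )
    s5d = np.sqrt(5.0) * d
    return signal_var * (1.0 + s5d + s5d**2 / 3.0) * np.exp(-s5d)


def dense_gp_posterior(model, X_test):
    """Brute-force GP equations with the model's fitted hyperparameters.

    Replays target standardization and the exact kernel matrix solve with
    explicit inverses, as an oracle for the packaged predict path.
    """
    params = model.hyperparameters
    signal = [v for k, v in params.items() if k.endswith("constant_value")][0]
    length = np.atleast_1d(
        [v for k, v in params.items() if k.endswith("length_scale")][0]
    )
    noise_entries = [v for k, v in params.items() if k.endswith("noise_level")]
    noise = noise_entries[0] if noise_entries else 0.0

    X, y = model.X_train, model.y_train
    y_mean, y_std = y.mean(), y.std(ddof=0)
    if y_std == 0:
        y_std = 1.0
    yz = (y - y_mean) / y_std

    K = matern52(X, X, length, signal) + (noise + model.regressor.alpha) * np.eye(len(X))
    K_inv = np.linalg.inv(K)
    Ks = matern52(X_test, X, length, signal)
    Kss = matern52(X_test, X_test, length, signal) + noise * np.eye(len(X_test))
    mu = Ks @ K_inv @ yz
    cov = Kss - Ks @ K_inv @ Ks.T
    return mu * y_std + y_mean, np.sqrt(np.maximum(np.diag(cov), 0.0)) * y_std


class TestFit:
    def test_refit_same_seed_identical(self, rng, fast_gp):
        X = rng.standard_normal((12, 3))
        y = rng.standard_normal(12)
        m1, m2 = fit(X, y, fast_gp), fit(X, y, fast_gp)
        assert m1.hyperparameters == m2.hyperparameters

    def test_constant_target_predicts_constant(self, rng, fast_gp):
        X = rng.standard_normal((10, 2))
        model = fit(X, np.full(10, 0.7), fast_gp)
        mean, _ = predict_arrays(model, rng.standard_normal((5, 2)))
        np.testing.assert_allclose(mean, 0.7, atol=1e-6)

    def test_optimization_beats_initial_hyperparameters(self, rng, fast_gp):
        X = rng.standard_normal((15, 2))
        y = np.sin(X[:, 0]) + 0.1 * rng.standard_normal(15)
        model = fit(X, y, fast_gp)
        reg = model.regressor
        lml_init = reg.log_marginal_likelihood(reg.kernel.theta)
        assert model.log_marginal_likelihood >= lml_init - 1e-8

    def test_non_finite_target_rejected(self, rng, fast_gp):
        X = rng.standard_normal((5, 2))
        with pytest.raises(ValidationError):
            fit(X, [0.1, 0.2, np.nan, 0.4, 0.5], fast_gp)


class TestPredict:
    def test_noise_free_interpolation(self, rng):
        cfg = GPConfig(noise=0.0, n_restarts=1)
        X = rng.standard_normal((8, 2))
        y = rng.uniform(0, 1, 8)
        model = fit(X, y, cfg)
        preds = predict(model, X)
        for p, yi in zip(preds, y):
            assert p.mean == pytest.approx(yi, abs=1e-4)
            assert p.std < 1e-3

    def test_prior_reversion_far_from_data(self, rng):
        cfg = GPConfig(noise=0.0, n_restarts=1)
        X = rng.standard_normal((8, 2))
        y = rng.uniform(0, 1, 8)
        model = fit(X, y, cfg)
        far = np.full((1, 2), 1e6)
        mean, std = predict_arrays(model, far)
        assert mean[0] == pytest.approx(y.mean(), abs=1e-6)
        prior_std = np.sqrt(
            [v for k, v in model.hyperparameters.items() if "constant" in k][0]
        ) * y.std(ddof=0)
        assert std[0] == pytest.approx(prior_std, rel=1e-3)

    def test_three_point_1d_matches_dense_oracle(self, fast_gp):
        X = np.array([[0.0], [1.0], [2.5]])
        y = np.array([0.2, 0.9, 0.4])
        model = fit(X, y, fast_gp)
        X_new = np.linspace(-1, 4, 7)[:, None]
        mean, std = predict_arrays(model, X_new)
        mu_o, sd_o = dense_gp_posterior(model, X_new)
        np.testing.assert_allclose(mean, mu_o, atol=1e-8)
        np.testing.assert_allclose(std, sd_o, atol=1e-6)

    def test_posterior_equivalence_property(self, rng, fast_gp):
        # dense-oracle agreement on random small datasets
        for _ in range(5):
            n = int(rng.integers(3, 21))
            d = int(rng.integers(1, 4))
            X = rng.standard_normal((n, d))
            y = rng.standard_normal(n)
            model = fit(X, y, fast_gp)
            X_new = rng.standard_normal((6, d))
            mean, std = predict_arrays(model, X_new)
            mu_o, sd_o = dense_gp_posterior(model, X_new)
            np.testing.assert_allclose(mean, mu_o, atol=1e-6)
            np.testing.assert_allclose(std, sd_o, atol=1e-6)

    def test_variance_never_exceeds_prior(self, rng):
        cfg = GPConfig(noise=0.0, n_restarts=1)
        X = rng.standard_normal((10, 2))
        y = rng.standard_normal(10)
        model = fit(X, y, cfg)
        _, std = predict_arrays(model, rng.standard_normal((40, 2)))
        prior_std = np.sqrt(
            [v for k, v in model.hyperparameters.items() if "constant" in k][0]
        ) * y.std(ddof=0)
        assert np.all(std <= prior_std * (1 + 1e-9))

    def test_conditioning_shrinks_variance(self, rng):
        cfg = GPConfig(noise=0.0, n_restarts=1)
        X = rng.standard_normal((8, 2))
        y = rng.standard_normal(8)
        model = fit(X, y, cfg)
        X_test = rng.standard_normal((20, 2))
        _, std_before = predict_arrays(model, X_test)
        x_new = rng.standard_normal((1, 2))
        grown = refit_fixed(
            model,
            np.vstack([X, x_new]),
            np.append(y, 0.3),
        )
        _, std_after = predict_arrays(grown, X_test)
        assert np.all(std_after <= std_before + 1e-6)

    def test_column_mismatch_rejected(self, rng, fast_gp):
        frame = pd.DataFrame(rng.standard_normal((6, 2)), columns=["a", "b"])
        model = fit(frame, rng.standard_normal(6), fast_gp)
        wrong = pd.DataFrame(rng.standard_normal((2, 2)), columns=["b", "a"])
        with pytest.raises(SchemaError):
            predict(model, wrong)


class TestCrossValidate:
    def test_fold_sizes_45_11_on_56_records(self, rng, fast_gp):
        frame = pd.DataFrame(rng.standard_normal((56, 3)))
        frame.columns = list("abc")
        y = rng.uniform(0, 1, 56)
        report = cross_validate(frame, y, k=5, seed=0, config=fast_gp)
        for tr, te in zip(report.fold_train_indices, report.fold_test_indices):
            assert (len(tr), len(te)) == (45, 11)
            assert set(tr).isdisjoint(te)

    def test_split_sizes_helper(self):
        assert split_sizes(56, 5) == (45, 11)
        assert split_sizes(55, 5) == (44, 11)

    def test_same_seed_identical_folds(self, rng, fast_gp):
        frame = pd.DataFrame(rng.standard_normal((20, 2)), columns=["a", "b"])
        y = rng.uniform(0, 1, 20)
        r1 = cross_validate(frame, y, k=4, seed=7, config=fast_gp)
        r2 = cross_validate(frame, y, k=4, seed=7, config=fast_gp)
        for a, b in zip(r1.fold_test_indices, r2.fold_test_indices):
            np.testing.assert_array_equal(a, b)

    def test_near_noiseless_linear_signal_is_learned(self, rng, fast_gp):
        X = rng.standard_normal((40, 2))
        y = X @ [0.3, -0.2] + 0.5
        frame = pd.DataFrame(X, columns=["a", "b"])
        report = cross_validate(frame, y, k=3, seed=1, config=fast_gp)
        assert report.rmse_mean < 0.05

    def test_k_larger_than_dataset_rejected(self, rng, fast_gp):
        frame = pd.DataFrame(rng.standard_normal((4, 2)), columns=["a", "b"])
        with pytest.raises(ValidationError):
            cross_validate(frame, rng.uniform(0, 1, 4), k=5, config=fast_gp)

    def test_informative_encoding_beats_one_hot(self, rng, fast_gp):
        # a planted additive signal: real-valued descriptors that carry it
        # should out-predict a purely categorical one-hot encoding
        n = 40
        latent = rng.standard_normal(n)
        y = 1 / (1 + np.exp(-latent))
        informative = pd.DataFrame(
            {
                "s": latent + 0.05 * rng.standard_normal(n),
                "junk": rng.standard_normal(n),
            }
        )
        one_hot = pd.DataFrame(np.eye(n))
        one_hot.columns = [f"id{i}" for i in range(n)]
        r_inf = cross_validate(informative, y, "dft-ingest", k=3, seed=2, config=fast_gp)
        r_ohe = cross_validate(one_hot, y, "one-hot", k=3, seed=2, config=fast_gp)
        assert r_inf.rmse_mean < r_ohe.rmse_mean
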