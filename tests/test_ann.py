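"""Inverse-model network: forward pass, Bayesian-regularized training."""

from dataclasses import replace

import numpy as np
import pytest

from etongue.ann import (
    AffineScaler,
    MLPModel,
    TrainingConfig,
    architecture_scan,
    forward,
    multi_restart_train,
    train,
)
from etongue.errors import ConfigError, InputError


def loop_forward_oracle(model, X):
    """Non-vectorized forward pass used as an independent oracle."""
    out = np.zeros((len(X), model.layer_sizes[2]))
    f = {"tansig": np.tanh, "purelin": lambda v: v,
         "logsig": lambda v: 1 / (1 + np.exp(-v))}[model.hidden_transfer]
    for n, x in enumerate(model.input_scaler.transform(X)):
        h = np.empty(model.layer_sizes[1])
        for i in range(model.layer_sizes[1]):
            acc = model.b1[i]
            for j in range(model.layer_sizes[0]):
                acc += model.W1[i, j] * x[j]
            h[i] = f(acc)
        for k in range(model.layer_sizes[2]):
            acc = model.b2[k]
            for i in range(model.layer_sizes[1]):
                acc += model.W2[k, i] * h[i]
            out[n, k] = acc
    return model.output_scaler.inverse(out)


def scaled_model(layer_sizes=(5, 8, 2), seed=0, transfer="tansig"):
    rng = np.random.default_rng(seed)
    m = MLPModel(layer_sizes=layer_sizes, hidden_transfer=transfer)
    m = replace(
        m,
        input_scaler=AffineScaler(
            lo=np.full(layer_sizes[0], -150.0), hi=np.full(layer_sizes[0], 250.0)
        ),
        output_scaler=AffineScaler(
            lo=np.zeros(layer_sizes[2]), hi=np.full(layer_sizes[2], 3.3e-4)
        ),
    )
    return m.init_weights(int(rng.integers(2**31 - 1)))


class TestForward:
    def test_zero_weights_give_output_scaling_midpoint(self):
        m = scaled_model()
        m = m.unpack(np.zeros(m.n_weights))
        X = np.random.default_rng(1).uniform(-100, 200, (7, 5))
        Y = forward(m, X)
        mid = (m.output_scaler.lo + m.output_scaler.hi) / 2
        assert np.allclose(Y, mid)

    def test_single_hidden_unit_matches_hand_evaluation(self):
        m = MLPModel(layer_sizes=(1, 1, 1))
        m = replace(
            m,
            W1=np.array([[2.0]]), b1=np.array([0.5]),
            W2=np.array([[-1.5]]), b2=np.array([0.25]),
            input_scaler=AffineScaler(lo=np.array([0.0]), hi=np.array([1.0])),
            output_scaler=AffineScaler(lo=np.array([-1.0]), hi=np.array([1.0])),
        )
        x = 0.3
        xs = 2 * x - 1
        expected = -1.5 * np.tanh(2 * xs + 0.5) + 0.25  # output scaling is identity
        assert forward(m, [[x]])[0, 0] == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("transfer", ["tansig", "purelin", "logsig"])
    def test_matches_loop_oracle_on_random_models(self, transfer, rng):
        for trial in range(5):
            m = scaled_model(seed=trial + 10, transfer=transfer)
            X = rng.uniform(-150, 250, (6, 5))
            assert np.allclose(forward(m, X), loop_forward_oracle(m, X), atol=1e-12)

    def test_extrapolation_flagged_not_rejected(self):
        m = scaled_model()
        _, flags = forward(m, np.full((1, 5), 1e4), return_extrapolation_flags=True)
        assert flags[0]

    def test_wrong_width_rejected(self):
        with pytest.raises(InputError):
            forward(scaled_model(), np.zeros((3, 4)))


@pytest.fixture(scope="module")
def linear_problem():
    rng = np.random.default_rng(3)
    X = rng.uniform(0.0, 200.0, (40, 5))
    A = rng.uniform(-1, 1, (5, 2)) * 1e-6
    Y = X @ A + 5e-5
    return X, Y


class TestTraining:
    def test_purelin_hidden_layer_recovers_linear_map(self, linear_problem):
        X, Y = linear_problem
        m = MLPModel(layer_sizes=(5, 4, 2), hidden_transfer="purelin")
        m, rep = train(m, X, Y, TrainingConfig(seed=7, max_epochs=200))
        pred = forward(m, X)
        assert np.sqrt(np.mean((pred - Y) ** 2)) < 1e-6

    def test_same_seed_gives_bitwise_identical_weights(self, linear_problem):
        X, Y = linear_problem
        cfg = TrainingConfig(seed=11, max_epochs=30)
        m1, _ = train(MLPModel(layer_sizes=(5, 4, 2)), X, Y, cfg)
        m2, _ = train(MLPModel(layer_sizes=(5, 4, 2)), X, Y, cfg)
        assert np.array_equal(m1.pack(), m2.pack())

    def test_objective_non_increasing_over_accepted_steps(self, linear_problem):
        X, Y = linear_problem
        m = MLPModel(layer_sizes=(5, 6, 2))
        _, rep = train(m, X, Y, TrainingConfig(seed=2, max_epochs=150))
        for before, after in rep.objective_path:
            assert after <= before

    def test_gamma_eff_stays_within_weight_count(self, linear_problem):
        X, Y = linear_problem
        m = MLPModel(layer_sizes=(5, 6, 2))
        _, rep = train(m, X, Y, TrainingConfig(seed=2, max_epochs=150))
        Nw = 5 * 6 + 6 + 6 * 2 + 2
        assert all(-1e-9 <= g <= Nw + 1e-9 for g in rep.gamma_path)
        assert 0 <= rep.gamma_eff <= Nw

    def test_fixed_zero_alpha_matches_linear_least_squares(self):
        # quadratic test problem: a purelin 'network' is an affine model, so
        # LM with alpha pinned at 0 must land on the OLS solution
        rng = np.random.default_rng(9)
        X = rng.uniform(-50, 150, (30, 3))
        Y = X @ np.array([[2e-6], [-1e-6], [5e-7]]) + 1e-5
        Y += rng.normal(0, 1e-6, Y.shape)
        m = MLPModel(layer_sizes=(3, 2, 1), hidden_transfer="purelin")
        cfg = TrainingConfig(
            seed=4, max_epochs=400, adapt_hyperparameters=False,
            initial_alpha=0.0, initial_beta=1.0,
        )
        m, _ = train(m, X, Y, cfg)
        pred = m and forward(m, X)
        # OLS oracle in raw units
        Xd = np.column_stack([X, np.ones(len(X))])
        coef, *_ = np.linalg.lstsq(Xd, Y, rcond=None)
        ols_pred = Xd @ coef
        assert np.sqrt(np.mean((pred - ols_pred) ** 2)) < 1e-8

    def test_prediction_invariant_to_input_units(self, linear_problem):
        # mV vs V: the scaling layer absorbs any affine reparameterization
        X, Y = linear_problem
        cfg = TrainingConfig(seed=13, max_epochs=120)
        m1, _ = train(MLPModel(layer_sizes=(5, 4, 2)), X, Y, cfg)
        m2, _ = train(MLPModel(layer_sizes=(5, 4, 2)), X / 1000.0, Y, cfg)
        assert np.allclose(forward(m1, X), forward(m2, X / 1000.0), rtol=1e-9)

    def test_too_few_rows_rejected(self):
        with pytest.raises(InputError):
            train(MLPModel(), np.zeros((5, 5)), np.zeros((5, 2)))


class TestRestartsAndScan:
    def test_multi_restart_reproducible_and_reports_dispersion(self, linear_problem):
        X, Y = linear_problem
        cfg = TrainingConfig(seed=21, max_epochs=60, n_restarts=3)
        template = MLPModel(layer_sizes=(5, 3, 2), hidden_transfer="purelin")
        m1, s1 = multi_restart_train(template, X[:30], Y[:30], X[30:], Y[30:], cfg)
        m2, s2 = multi_restart_train(template, X[:30], Y[:30], X[30:], Y[30:], cfg)
        assert np.array_equal(m1.pack(), m2.pack())
        assert s1.test_rmse == s2.test_rmse
        assert len(s1.test_rmse) == 3
        # realizable noise-free target: restart dispersion is tiny
        assert s1.test_rmse_sd < 10 * max(s1.test_rmse)

    def test_scan_marks_minimum_rmse_configuration(self, linear_problem):
        X, Y = linear_problem
        cfg = TrainingConfig(seed=5, max_epochs=40, n_restarts=2)
        table, models = architecture_scan(
            [2, 4], ["purelin"], X[:30], Y[:30], X[30:], Y[30:], cfg,
            ion_names=("a", "b"),
        )
        assert len(table) == 2
        assert table["selected"].sum() == 1
        sel = table[table["selected"]].iloc[0]
        assert sel["rmse_test"] == table["rmse_test"].min()

    def test_restart_count_must_be_at_least_two(self, linear_problem):
        X, Y = linear_problem
        with pytest.raises(InputError):
            multi_restart_train(
                MLPModel(), X, Y, X, Y, TrainingConfig(n_restarts=1)
            )


def test_model_validation():
    with pytest.raises(ConfigError):
        MLPModel(layer_sizes=(5, 8))
    with pytest.raises(ConfigError):
        MLPModel(hidden_transfer="relu")
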