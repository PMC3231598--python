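"""Inverse response model: a small MLP trained with Bayesian regularization.

The network maps the array's potentials (five inputs, mV) to the two ion
concentrations (mol/L).  Architecture: one hidden layer (default eight
units, hyperbolic-tangent transfer) and a linear output layer; inputs and
outputs are min-max scaled to [-1, 1] using the training subset only.

Training minimizes the regularized objective

    F = beta * E_D + alpha * E_W,   E_D = sum of squared (scaled) errors,
                                    E_W = sum of squared weights,

by Levenberg-Marquardt steps with an adaptive damping factor.  The
hyperparameters follow MacKay's evidence framework as popularized by
Foresee & Hagan: with H ~= 2*beta*J'J + 2*alpha*I,

    gamma = N_w - 2*alpha*tr(H^-1)      (effective number of parameters)
    alpha <- gamma / (2 E_W)
    beta  <- (n - gamma) / (2 E_D)

which automatically balances data fit against weight decay and removes the
need for a separate validation subset.  A plain gradient-descent-with-
momentum strategy is provided as a fallback; it is the only strategy that
honours the ``learning_rate``/``momentum`` settings (the regularized LM
updates are governed by the damping schedule instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigError, ConvergenceError, InputError

__all__ = [
    "AffineScaler",
    "MLPModel",
    "TrainingConfig",
    "TrainingReport",
    "forward",
    "train",
    "multi_restart_train",
    "architecture_scan",
]

_TRANSFERS: dict[str, tuple[Callable, Callable]] = {
    # name -> (f, f' expressed in terms of the *output* of f)
    "tansig": (np.tanh, lambda y: 1.0 - y**2),
    "purelin": (lambda x: x, lambda y: np.ones_like(y)),
    "logsig": (lambda x: 1.0 / (1.0 + np.exp(-x)), lambda y: y * (1.0 - y)),
}


@dataclass
class AffineScaler:
    """Per-dimension min-max map onto [-1, 1] (constant dims map to 0)."""

    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def from_data(cls, X: np.ndarray) -> "AffineScaler":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return cls(lo=X.min(axis=0), hi=X.max(axis=0))

    @property
    def span(self) -> np.ndarray:
        span = self.hi - self.lo
        return np.where(span > 0, span, 1.0)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return 2.0 * (np.asarray(X, dtype=float) - self.lo) / self.span - 1.0

    def inverse(self, Xs: np.ndarray) -> np.ndarray:
        return (np.asarray(Xs, dtype=float) + 1.0) / 2.0 * self.span + self.lo


@dataclass
class MLPModel:
    """Weights, transfer functions and scaling of the inverse model."""

    layer_sizes: tuple[int, int, int] = (5, 8, 2)
    hidden_transfer: str = "tansig"
    output_transfer: str = "purelin"
    W1: np.ndarray | None = None
    b1: np.ndarray | None = None
    W2: np.ndarray | None = None
    b2: np.ndarray | None = None
    input_scaler: AffineScaler | None = None
    output_scaler: AffineScaler | None = None

    def __post_init__(self) -> None:
        if len(self.layer_sizes) != 3:
            raise ConfigError("layer_sizes must be (n_in, n_hidden, n_out)")
        if self.hidden_transfer not in _TRANSFERS:
            raise ConfigError(f"unknown hidden transfer {self.hidden_transfer!r}")
        if self.output_transfer != "purelin":
            raise ConfigError("the output layer is linear by construction")
        n_in, H, n_out = self.layer_sizes
        if self.W1 is None:
            self.W1 = np.zeros((H, n_in))
            self.b1 = np.zeros(H)
            self.W2 = np.zeros((n_out, H))
            self.b2 = np.zeros(n_out)
        shapes = (self.W1.shape, self.b1.shape, self.W2.shape, self.b2.shape)
        if shapes != ((H, n_in), (H,), (n_out, H), (n_out,)):
            raise ConfigError(f"inconsistent weight shapes {shapes}")

    @property
    def n_weights(self) -> int:
        n_in, H, n_out = self.layer_sizes
        return H * n_in + H + n_out * H + n_out

    def init_weights(self, seed: int) -> "MLPModel":
        """Fresh copy with weights drawn uniformly from [-0.5, 0.5]."""
        rng = np.random.default_rng(seed)
        n_in, H, n_out = self.layer_sizes
        return replace(
            self,
            W1=rng.uniform(-0.5, 0.5, (H, n_in)),
            b1=rng.uniform(-0.5, 0.5, H),
            W2=rng.uniform(-0.5, 0.5, (n_out, H)),
            b2=rng.uniform(-0.5, 0.5, n_out),
        )

    def pack(self) -> np.ndarray:
        return np.concatenate(
            [self.W1.ravel(), self.b1, self.W2.ravel(), self.b2]
        )

    def unpack(self, w: np.ndarray) -> "MLPModel":
        n_in, H, n_out = self.layer_sizes
        i = 0
        W1 = w[i : i + H * n_in].reshape(H, n_in); i += H * n_in
        b1 = w[i : i + H]; i += H
        W2 = w[i : i + n_out * H].reshape(n_out, H); i += n_out * H
        b2 = w[i : i + n_out]
        return replace(self, W1=W1, b1=b1, W2=W2, b2=b2)


def _forward_scaled(model: MLPModel, Xs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scaled-space forward pass; returns (hidden outputs, scaled outputs)."""
    f, _ = _TRANSFERS[model.hidden_transfer]
    Hout = f(Xs @ model.W1.T + model.b1)
    return Hout, Hout @ model.W2.T + model.b2


def forward(
    model: MLPModel,
    potentials: np.ndarray,
    return_extrapolation_flags: bool = False,
):
    """Predict concentrations (mol/L) from raw potentials (mV).

    Inputs well outside the training range are flagged (not rejected): the
    model is then extrapolating and its error bounds no longer apply.
    """
    X = np.atleast_2d(np.asarray(potentials, dtype=float))
    if X.shape[1] != model.layer_sizes[0]:
        raise InputError(
            f"expected {model.layer_sizes[0]} sensor columns, got {X.shape[1]}"
        )
    if model.input_scaler is None or model.output_scaler is None:
        raise InputError("model has no fitted input/output scaling")
    Xs = model.input_scaler.transform(X)
    _, Ys = _forward_scaled(model, Xs)
    Y = model.output_scaler.inverse(Ys)
    if return_extrapolation_flags:
        flags = np.any(np.abs(Xs) > 1.05, axis=1)
        return Y, flags
    return Y


def _jacobian(model: MLPModel, Xs: np.ndarray) -> np.ndarray:
    """Jacobian of the scaled outputs w.r.t. the packed weight vector.

    Rows follow the C-order raveling of the (n_samples, n_out) output array,
    matching the residual vector layout used in training.
    """
    n, n_in = Xs.shape
    _, H, n_out = model.layer_sizes
    f, fprime = _TRANSFERS[model.hidden_transfer]
    Hout = f(Xs @ model.W1.T + model.b1)  # (n, H)
    D = fprime(Hout)  # (n, H)
    Nw = model.n_weights
    J = np.zeros((n, n_out, Nw))
    # d y_k / d W1[h, i] = W2[k, h] * D[:, h] * Xs[:, i]
    dW1 = np.einsum("kh,nh,ni->nkhi", model.W2, D, Xs)
    J[:, :, : H * n_in] = dW1.reshape(n, n_out, H * n_in)
    i0 = H * n_in
    J[:, :, i0 : i0 + H] = np.einsum("kh,nh->nkh", model.W2, D)
    i0 += H
    # d y_k / d W2[k, h] = Hout[:, h]
    dW2 = np.zeros((n, n_out, n_out, H))
    for k in range(n_out):
        dW2[:, k, k, :] = Hout
    J[:, :, i0 : i0 + n_out * H] = dW2.reshape(n, n_out, n_out * H)
    i0 += n_out * H
    for k in range(n_out):
        J[:, k, i0 + k] = 1.0
    return J.reshape(n * n_out, Nw)


@dataclass(frozen=True)
class TrainingConfig:
    strategy: str = "bayesian_regularization"
    learning_rate: float = 0.1  # used by gradient_descent_momentum only
    momentum: float = 0.4  # used by gradient_descent_momentum only
    max_epochs: int = 300
    ftol: float = 1e-9  # objective-change tolerance
    patience: int = 10  # consecutive small-change epochs before stopping
    n_restarts: int = 5
    seed: int = 0
    mu0: float = 1e-3  # initial LM damping
    mu_max: float = 1e10
    adapt_hyperparameters: bool = True  # evidence updates of alpha/beta
    # epochs of plain LM descent before the first evidence update: the
    # re-estimation formulas assume the weights sit near a posterior optimum,
    # and applying them from a random initialization (large misfit, tiny
    # weight norm) locks in an excessive weight decay
    hyperparameter_warmup_epochs: int = 10
    initial_alpha: float = 0.0
    initial_beta: float = 1.0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.max_epochs < 1:
            raise ConfigError("learning_rate must be > 0 and max_epochs >= 1")
        if self.n_restarts < 1:
            raise ConfigError("n_restarts must be >= 1")


@dataclass
class TrainingReport:
    objective_path: list[tuple[float, float]] = field(default_factory=list)
    gamma_path: list[float] = field(default_factory=list)
    alpha: float = 0.0
    beta: float = 1.0
    gamma_eff: float = 0.0
    n_epochs: int = 0
    converged: bool = False
    train_rmse_scaled: float = np.nan


def _trace_inverse(H: np.ndarray) -> float:
    try:
        return float(np.trace(np.linalg.inv(H)))
    except np.linalg.LinAlgError:
        return float(np.trace(np.linalg.pinv(H)))


def train(
    model: MLPModel,
    X: np.ndarray,
    Y: np.ndarray,
    config: TrainingConfig | None = None,
) -> tuple[MLPModel, TrainingReport]:
    """Train the inverse model on raw potentials X (mV) and targets Y (mol/L).

    Scaling is (re)computed from the given data when the model carries none,
    so the training subset defines the scaled space.  The run is a pure
    function of (model weights, data, config.seed).
    """
    config = config or TrainingConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if len(X) != len(Y):
        raise InputError("X and Y differ in length")
    if len(X) < 10:
        raise InputError("at least 10 training rows are required")
    if model.input_scaler is None:
        model = replace(model, input_scaler=AffineScaler.from_data(X))
    if model.output_scaler is None:
        model = replace(model, output_scaler=AffineScaler.from_data(Y))
    if not np.any(model.pack()):
        model = model.init_weights(config.seed)
    if config.strategy == "gradient_descent_momentum":
        return _train_gdm(model, X, Y, config)
    if config.strategy != "bayesian_regularization":
        raise ConfigError(f"unknown training strategy {config.strategy!r}")

    Xs = model.input_scaler.transform(X)
    Ys = model.output_scaler.transform(Y)
    n = Ys.size
    w = model.pack()
    Nw = model.n_weights
    alpha, beta = config.initial_alpha, config.initial_beta
    mu = config.mu0
    report = TrainingReport(alpha=alpha, beta=beta)

    def residuals(wvec: np.ndarray) -> np.ndarray:
        _, out = _forward_scaled(model.unpack(wvec), Xs)
        return (Ys - out).ravel()

    e = residuals(w)
    ED = float(e @ e)
    EW = float(w @ w)
    small_steps = 0
    eye = np.eye(Nw)
    for epoch in range(config.max_epochs):
        J = _jacobian(model.unpack(w), Xs)
        H = 2.0 * beta * (J.T @ J) + 2.0 * alpha * eye
        if config.adapt_hyperparameters and epoch >= config.hyperparameter_warmup_epochs:
            gamma = Nw - 2.0 * alpha * _trace_inverse(H)
            alpha = gamma / (2.0 * EW) if EW > 1e-300 else alpha
            if n > gamma:
                beta = (n - gamma) / (2.0 * ED) if ED > 1e-300 else beta
            H = 2.0 * beta * (J.T @ J) + 2.0 * alpha * eye
            report.gamma_path.append(float(gamma))
        g = -2.0 * beta * (J.T @ e) + 2.0 * alpha * w
        F = beta * ED + alpha * EW
        accepted = False
        singular = 0
        while mu <= config.mu_max:
            try:
                delta = np.linalg.solve(H + mu * eye, -g)
            except np.linalg.LinAlgError:
                singular += 1
                if singular > 60:
                    raise ConvergenceError(
                        "LM normal equations remained singular across the "
                        "whole damping schedule"
                    )
                mu *= 10.0
                continue
            w_new = w + delta
            e_new = residuals(w_new)
            ED_new = float(e_new @ e_new)
            EW_new = float(w_new @ w_new)
            F_new = beta * ED_new + alpha * EW_new
            if F_new < F:
                w, e, ED, EW = w_new, e_new, ED_new, EW_new
                mu = max(mu / 10.0, 1e-20)
                accepted = True
                report.objective_path.append((float(F), float(F_new)))
                break
            mu *= 10.0
        report.n_epochs = epoch + 1
        if not accepted:
            # damping exhausted without descent: gradient is numerically flat
            report.converged = True
            break
        F_after = beta * ED + alpha * EW
        if abs(F - F_after) < config.ftol:
            small_steps += 1
            if small_steps >= config.patience:
                report.converged = True
                break
        else:
            small_steps = 0

    model = model.unpack(w)
    H = 2.0 * beta * (J.T @ J) + 2.0 * alpha * eye
    report.alpha, report.beta = float(alpha), float(beta)
    report.gamma_eff = float(Nw - 2.0 * alpha * _trace_inverse(H))
    report.train_rmse_scaled = float(np.sqrt(ED / n))
    return model, report


def _train_gdm(
    model: MLPModel, X: np.ndarray, Y: np.ndarray, config: TrainingConfig
) -> tuple[MLPModel, TrainingReport]:
    """Batch gradient descent with momentum on the mean squared error."""
    Xs = model.input_scaler.transform(X)
    Ys = model.output_scaler.transform(Y)
    n = Ys.size
    w = model.pack()
    v = np.zeros_like(w)
    report = TrainingReport(alpha=0.0, beta=1.0)
    prev = np.inf
    small_steps = 0
    for epoch in range(config.max_epochs):
        m = model.unpack(w)
        _, out = _forward_scaled(m, Xs)
        e = (Ys - out).ravel()
        mse = float(e @ e) / n
        J = _jacobian(m, Xs)
        grad = -2.0 * (J.T @ e) / n
        v = config.momentum * v - config.learning_rate * grad
        w = w + v
        report.objective_path.append((prev if np.isfinite(prev) else mse, mse))
        if abs(prev - mse) < config.ftol:
            small_steps += 1
            if small_steps >= config.patience:
                report.converged = True
                break
        else:
            small_steps = 0
        prev = mse
        report.n_epochs = epoch + 1
    model = model.unpack(w)
    _, out = _forward_scaled(model, Xs)
    e = (Ys - out).ravel()
    report.train_rmse_scaled = float(np.sqrt((e @ e) / n))
    return model, report


@dataclass
class RestartSummary:
    best_index: int
    test_rmse: tuple[float, ...]
    test_rmse_sd: float
    reports: tuple[TrainingReport, ...]


def multi_restart_train(
    model_template: MLPModel,
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_test: np.ndarray,
    Y_test: np.ndarray,
    config: TrainingConfig | None = None,
) -> tuple[MLPModel, RestartSummary]:
    """Train ``n_restarts`` times from random weights; keep the best by test RMSE.

    The spread of the restart RMSEs estimates the precision of the model
    (sensitivity to initialization), reported alongside the point estimate.
    """
    config = config or TrainingConfig()
    if config.n_restarts < 2:
        raise InputError("multi_restart_train requires n_restarts >= 2")
    seeds = [
        int(s.generate_state(1)[0] % (2**31 - 1))
        for s in np.random.SeedSequence(config.seed).spawn(config.n_restarts)
    ]
    scaler_x = AffineScaler.from_data(X_train)
    scaler_y = AffineScaler.from_data(Y_train)
    best: tuple[float, MLPModel] | None = None
    rmses: list[float] = []
    reports: list[TrainingReport] = []
    best_index = -1
    for i, seed in enumerate(seeds):
        m = replace(
            model_template, input_scaler=scaler_x, output_scaler=scaler_y
        ).init_weights(seed)
        m, rep = train(m, X_train, Y_train, replace(config, seed=seed))
        pred = forward(m, X_test)
        rmse = float(np.sqrt(np.mean((pred - Y_test) ** 2)))
        rmses.append(rmse)
        reports.append(rep)
        if best is None or rmse < best[0]:
            best = (rmse, m)
            best_index = i
    if best is None:
        raise ConvergenceError("all restarts failed")
    summary = RestartSummary(
        best_index=best_index,
        test_rmse=tuple(rmses),
        test_rmse_sd=float(np.std(rmses, ddof=1)),
        reports=tuple(reports),
    )
    return best[1], summary


def architecture_scan(
    h_values: Sequence[int],
    transfer_options: Sequence[str],
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_test: np.ndarray,
    Y_test: np.ndarray,
    config: TrainingConfig | None = None,
    ion_names: Sequence[str] = ("ClO4", "S"),
):
    """Systematic scan of hidden-layer size and transfer function.

    Each configuration is trained with restarts (best kept); the returned
    table carries pooled and per-ion test RMSE plus obtained-vs-expected
    regression parameters, and marks the configuration with the smallest
    pooled test RMSE as selected.
    """
    import pandas as pd

    from .evaluate import comparison_regression, rmse

    if len(h_values) < 1:
        raise InputError("at least one hidden-layer size is required")
    config = config or TrainingConfig()
    rows = []
    models = {}
    for H in h_values:
        for transfer in transfer_options:
            row: dict[str, object] = {"H": int(H), "transfer": transfer}
            try:
                template = MLPModel(
                    layer_sizes=(X_train.shape[1], int(H), Y_train.shape[1]),
                    hidden_transfer=transfer,
                )
                m, summary = multi_restart_train(
                    template, X_train, Y_train, X_test, Y_test, config
                )
                pred = forward(m, X_test)
                res = rmse(pred, Y_test, ion_names=ion_names)
                row["rmse_test"] = res.pooled
                row["rmse_sd_restarts"] = summary.test_rmse_sd
                for j, name in enumerate(ion_names):
                    reg = comparison_regression(
                        pred[:, j], Y_test[:, j], ion=name, subset="test"
                    )
                    row[f"rmse_{name}"] = res.per_ion[name]
                    row[f"slope_{name}"] = reg.slope
                    row[f"intercept_{name}"] = reg.intercept
                    row[f"r_{name}"] = reg.r
                row["status"] = "ok"
                models[(int(H), transfer)] = m
            except Exception as exc:  # scan continues; failures are recorded
                row["status"] = f"error: {exc}"
                row["rmse_test"] = np.nan
            rows.append(row)
    table = pd.DataFrame(rows)
    ok = table["rmse_test"].notna()
    table["selected"] = False
    if ok.any():
        table.loc[table.loc[ok, "rmse_test"].idxmin(), "selected"] = True
    return table, models
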