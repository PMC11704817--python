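"""Nomogram models mapping corneal power vectors to reconstructed corneal power.

Two predictor families are provided, both taking a preoperative corneal
power vector (EQ, C0, C45) — from keratometry or from total corneal power —
and returning the predicted reconstructed corneal power (RCP) vector:

* :class:`LinearMapModel` (REG): a multivariate linear regression,
  ``predicted = W @ x + b`` with a 3x3 weight matrix and a 3-vector
  intercept.  The published coefficient sets are available through
  :func:`published_nomogram`; new ones can be fitted by maximum likelihood
  with :func:`fit_linear_map` (for multivariate-normal residuals the ML
  optimum coincides with per-component least squares).

* :class:`NetworkModel` (NET): a shallow feedforward network with two hidden
  layers of 12 and 8 tanh units and a linear 3-unit output, trained on
  z-scored inputs and outputs by :func:`fit_network`.

Models are trained and applied in the right-eye convention; left-eye inputs
are mirrored (C45 sign-flip) on the way in and the prediction mirrored back
on the way out by :func:`predict_rcp`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import published
from .powervector import PowerVector, mirror_for_left_eye

__all__ = [
    "LinearMapModel",
    "NetworkModel",
    "FitReport",
    "published_nomogram",
    "predict_rcp",
    "fit_linear_map",
    "fit_network",
    "split_train_test",
    "model_loglik",
    "save_model",
    "load_model",
]


def _as_matrix(X) -> np.ndarray:
    """Stack PowerVectors (or array-likes) into an (n, 3) float array."""
    if isinstance(X, np.ndarray):
        return np.atleast_2d(np.asarray(X, dtype=float))
    rows = [x.as_array() if isinstance(x, PowerVector) else np.asarray(x, float) for x in X]
    return np.vstack(rows)


@dataclass(frozen=True)
class LinearMapModel:
    """3x3 linear map with intercept: predicted = matrix @ x + intercept."""

    matrix: np.ndarray
    intercept: np.ndarray
    source_label: str = "unlabelled"

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", np.asarray(self.matrix, float).reshape(3, 3))
        object.__setattr__(self, "intercept", np.asarray(self.intercept, float).reshape(3))

    def predict_array(self, X: np.ndarray) -> np.ndarray:
        X = _as_matrix(X)
        return X @ self.matrix.T + self.intercept

    def predict(self, pv: PowerVector) -> PowerVector:
        return PowerVector.from_array(self.matrix @ pv.as_array() + self.intercept)


_ACTIVATIONS = {"tanh": np.tanh, "identity": lambda z: z}


@dataclass(frozen=True)
class NetworkModel:
    """Feedforward 3-12-8-3 regression network with stored standardization.

    Weights follow the column convention ``z_next = z @ W + b``.  Inputs are
    z-scored with (x_mean, x_std) before the forward pass and outputs
    de-standardized with (y_mean, y_std), so prediction is deterministic and
    self-contained given the stored parameters.
    """

    weights: tuple  # tuple of 2-D arrays
    biases: tuple  # tuple of 1-D arrays
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray
    activation: str = "tanh"
    seed: int | None = None
    source_label: str = "unlabelled"

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", tuple(np.asarray(w, float) for w in self.weights))
        object.__setattr__(self, "biases", tuple(np.asarray(b, float) for b in self.biases))
        for name in ("x_mean", "x_std", "y_mean", "y_std"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float).reshape(-1))
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def hidden_layer_sizes(self) -> tuple:
        return tuple(w.shape[1] for w in self.weights[:-1])

    def predict_array(self, X: np.ndarray) -> np.ndarray:
        act = _ACTIVATIONS[self.activation]
        z = (_as_matrix(X) - self.x_mean) / self.x_std
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            z = act(z @ W + b)
        z = z @ self.weights[-1] + self.biases[-1]
        return z * self.y_std + self.y_mean

    def predict(self, pv: PowerVector) -> PowerVector:
        return PowerVector.from_array(self.predict_array(pv.as_array())[0])


@dataclass(frozen=True)
class FitReport:
    """Fit diagnostics: log-likelihood and per-split error metrics.

    mse is the generalized mean squared error (mean squared Euclidean norm
    of the 3-component residual, D^2); mdv the mean difference vector (mean
    Euclidean norm, D).  Jensen's inequality guarantees mdv <= sqrt(mse).
    """

    logL: float
    n_train: int
    mse_train: float
    mdv_train: float
    n_test: int = 0
    mse_test: float = float("nan")
    mdv_test: float = float("nan")
    converged: bool = True
    extra: dict = field(default_factory=dict)


def published_nomogram(source: str) -> LinearMapModel:
    """Return the published multilinear RCP nomogram.

    Parameters
    ----------
    source:
        ``"keratometry"`` for the preoperative-keratometry model or
        ``"total_corneal_power"`` for the total-corneal-power model.
    """
    if source == "keratometry":
        return LinearMapModel(
            published.KERATOMETRY_MATRIX,
            published.KERATOMETRY_INTERCEPT,
            "published-keratometry",
        )
    if source == "total_corneal_power":
        return LinearMapModel(
            published.TOTAL_CORNEAL_POWER_MATRIX,
            published.TOTAL_CORNEAL_POWER_INTERCEPT,
            "published-total-corneal-power",
        )
    raise ValueError(
        "source must be 'keratometry' or 'total_corneal_power', " f"got {source!r}"
    )


def predict_rcp(model, pv: PowerVector, laterality: str = "OD") -> PowerVector:
    """Apply an RCP nomogram with laterality handling.

    Models are trained in the right-eye convention; for a left eye (OS) the
    input C45 is sign-flipped before prediction and the output C45 flipped
    back, so the prediction respects the mirror symmetry of the eyes.
    """
    if laterality not in ("OD", "OS"):
        raise ValueError(f"laterality must be 'OD' or 'OS', got {laterality!r}")
    if laterality == "OS":
        return mirror_for_left_eye(model.predict(mirror_for_left_eye(pv)))
    return model.predict(pv)


def _metrics(residuals: np.ndarray) -> tuple:
    norms2 = np.sum(residuals**2, axis=1)
    return float(np.mean(norms2)), float(np.mean(np.sqrt(norms2)))


def model_loglik(model, X, Y) -> float:
    """Gaussian log-likelihood of the model residuals at the ML covariance.

    With residual covariance estimated from the residuals themselves (the ML
    plug-in), the log-likelihood reduces to
    ``-n/2 * (d*log(2*pi) + log det(Sigma_hat) + d)`` for d-dimensional
    residuals.  Works for any model exposing ``predict_array``, or pass
    ``model=None`` with Y already holding residuals in X's place.
    """
    Xm, Ym = _as_matrix(X), _as_matrix(Y)
    resid = Ym - model.predict_array(Xm) if model is not None else Ym - Xm
    n, d = resid.shape
    # the model, not the sample mean, is the location: do not re-centre
    sigma = resid.T @ resid / n + np.finfo(float).eps * np.eye(d)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular residual covariance")
    return float(-0.5 * n * (d * np.log(2.0 * np.pi) + logdet + d))


def fit_linear_map(
    X: Sequence[PowerVector], Y: Sequence[PowerVector]
) -> tuple[LinearMapModel, FitReport]:
    """Maximum-likelihood multivariate linear regression of Y on X.

    For multivariate-normal residuals the ML estimate equals per-component
    ordinary least squares with intercept, solved here in one lstsq call.
    Raises on rank-deficient designs and on fewer than 4 paired rows.
    """
    Xm, Ym = _as_matrix(X), _as_matrix(Y)
    if Xm.shape[0] != Ym.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    n = Xm.shape[0]
    if n < 4:
        raise ValueError(f"need at least 4 paired observations, got {n}")
    design = np.hstack([Xm, np.ones((n, 1))])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient design (rank {rank} < {design.shape[1]})"
        )
    coef, *_ = np.linalg.lstsq(design, Ym, rcond=None)
    model = LinearMapModel(coef[:-1].T, coef[-1], "fitted-linear")
    resid = Ym - model.predict_array(Xm)
    mse, mdv = _metrics(resid)
    report = FitReport(
        logL=model_loglik(model, Xm, Ym),
        n_train=n,
        mse_train=mse,
        mdv_train=mdv,
    )
    return model, report


def fit_network(
    X: Sequence[PowerVector],
    Y: Sequence[PowerVector],
    seed: int = 0,
    hidden_layer_sizes: tuple = (12, 8),
    activation: str = "tanh",
    max_iter: int = 4000,
    early_stopping: bool = True,
    validation_fraction: float = 0.15,
    n_iter_no_change: int = 50,
    tol: float = 1e-7,
    source_label: str = "fitted-network",
) -> tuple[NetworkModel, FitReport]:
    """Train the shallow feedforward RCP network (default 3-12-8-3, tanh).

    Inputs and outputs are z-scored (EQ sits near 44 D while the astigmatism
    components sit near 0, so raw-scale training is badly conditioned); the
    standardization parameters are stored in the returned model.  Training is
    deterministic given ``seed``.  Early stopping monitors a held-out 15% of
    the training data.  Non-convergence within ``max_iter`` is reported via
    ``FitReport.converged`` and a warning from the underlying optimizer, not
    silently ignored.
    """
    from sklearn.neural_network import MLPRegressor

    Xm, Ym = _as_matrix(X), _as_matrix(Y)
    if Xm.shape[0] != Ym.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    if Xm.shape[0] < 50:
        raise ValueError(f"need at least 50 paired observations, got {Xm.shape[0]}")
    x_mean, x_std = Xm.mean(axis=0), Xm.std(axis=0)
    y_mean, y_std = Ym.mean(axis=0), Ym.std(axis=0)
    x_std = np.where(x_std > 0, x_std, 1.0)
    y_std = np.where(y_std > 0, y_std, 1.0)
    Xs, Ys = (Xm - x_mean) / x_std, (Ym - y_mean) / y_std

    net = MLPRegressor(
        hidden_layer_sizes=hidden_layer_sizes,
        activation=activation,
        solver="adam",
        random_state=seed,
        max_iter=max_iter,
        early_stopping=early_stopping,
        validation_fraction=validation_fraction,
        n_iter_no_change=n_iter_no_change,
        tol=tol,
    )
    net.fit(Xs, Ys)
    converged = net.n_iter_ < max_iter
    model = NetworkModel(
        weights=tuple(net.coefs_),
        biases=tuple(net.intercepts_),
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        y_std=y_std,
        activation=activation,
        seed=seed,
        source_label=source_label,
    )
    resid = Ym - model.predict_array(Xm)
    mse, mdv = _metrics(resid)
    report = FitReport(
        logL=model_loglik(model, Xm, Ym),
        n_train=Xm.shape[0],
        mse_train=mse,
        mdv_train=mdv,
        converged=converged,
        extra={"n_iter": int(net.n_iter_)},
    )
    return model, report


def split_train_test(records: Sequence, fraction_train: float = 0.7, seed: int = 0):
    """Random disjoint, exhaustive train/test split, reproducible under seed.

    The training set holds ``round(fraction_train * N)`` records.  Refuses
    fewer than 10 records.
    """
    if not (0.0 < fraction_train < 1.0):
        raise ValueError("fraction_train must lie in (0, 1)")
    records = list(records)
    n = len(records)
    if n < 10:
        raise ValueError(f"need at least 10 records to split, got {n}")
    n_train = int(round(fraction_train * n))
    order = np.random.default_rng(seed).permutation(n)
    train = [records[i] for i in order[:n_train]]
    test = [records[i] for i in order[n_train:]]
    return train, test


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def save_model(model, path) -> None:
    """Serialize a LinearMapModel or NetworkModel to a JSON file."""
    if isinstance(model, LinearMapModel):
        payload = {
            "type": "linear",
            "matrix": model.matrix.tolist(),
            "intercept": model.intercept.tolist(),
            "source_label": model.source_label,
        }
    elif isinstance(model, NetworkModel):
        payload = {
            "type": "network",
            "weights": [w.tolist() for w in model.weights],
            "biases": [b.tolist() for b in model.biases],
            "x_mean": model.x_mean.tolist(),
            "x_std": model.x_std.tolist(),
            "y_mean": model.y_mean.tolist(),
            "y_std": model.y_std.tolist(),
            "activation": model.activation,
            "seed": model.seed,
            "source_label": model.source_label,
        }
    else:
        raise TypeError(f"cannot serialize model of type {type(model).__name__}")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path):
    """Load a model written by :func:`save_model`."""
    with open(path) as fh:
        payload = json.load(fh)
    kind = payload.get("type")
    if kind == "linear":
        return LinearMapModel(
            payload["matrix"], payload["intercept"], payload.get("source_label", "loaded")
        )
    if kind == "network":
        return NetworkModel(
            weights=tuple(payload["weights"]),
            biases=tuple(payload["biases"]),
            x_mean=payload["x_mean"],
            x_std=payload["x_std"],
            y_mean=payload["y_mean"],
            y_std=payload["y_std"],
            activation=payload.get("activation", "tanh"),
            seed=payload.get("seed"),
            source_label=payload.get("source_label", "loaded"),
        )
    raise ValueError(f"unknown model type {kind!r} in {path}")
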