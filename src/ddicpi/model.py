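"""L2-regularized logistic regression over pair features.

The classifier minimizes the penalized negative log-likelihood

    L(w, b) = -sum_i [ y_i log p_i + (1 - y_i) log(1 - p_i) ] + (lambda/2) ||w||^2

with p_i = sigmoid(b + w . x_i) computed on z-scored features; the intercept
is unpenalized and the scaler (per-feature mean/sd from the training data) is
stored inside the model so prediction is self-contained.  Optimization is
deterministic: an L-BFGS-B warm start followed by damped Newton steps until
the gradient max-norm falls below 1e-9 (well inside the 1e-6 convergence
contract), so refitting the same data always reproduces the same weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.linalg import cho_factor, cho_solve

from .errors import (
    DegenerateLabelsError,
    ModelFileError,
    PanelMismatchError,
    ValidationError,
)

MODEL_FORMAT_VERSION = 1

#: default gradient max-norm at which training declares convergence
GRAD_TOL = 1e-9
MAX_NEWTON_ITER = 200


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _log1p_exp(z: np.ndarray) -> np.ndarray:
    """log(1 + exp(z)) without overflow."""
    return np.where(z > 0, z + np.log1p(np.exp(-np.abs(z))), np.log1p(np.exp(z)))


@dataclass
class LogisticModel:
    """Fitted L2 logistic classifier with its feature scaler."""

    weights: np.ndarray
    intercept: float
    lam: float
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        p = len(self.feature_names)
        if not (
            self.weights.shape == (p,)
            and self.scaler_mean.shape == (p,)
            and self.scaler_sd.shape == (p,)
        ):
            raise ValidationError("weights/scaler/feature_names length mismatch")
        if np.any(self.scaler_sd <= 0):
            raise ValidationError("scaler sds must be positive")
        if self.lam < 0:
            raise ValidationError("lambda must be >= 0")

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scaler_mean) / self.scaler_sd

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise PanelMismatchError(
                f"expected {len(self.feature_names)} features, got "
                f"{X.shape[1] if X.ndim == 2 else X.shape}"
            )
        return self.intercept + self.standardize(X) @ self.weights


def _prepare(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValidationError("X must be 2-D with one label per row")
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 rows to train")
    if not np.all(np.isfinite(X)):
        raise ValidationError("features contain non-finite values")
    if set(np.unique(y)) != {0.0, 1.0}:
        raise DegenerateLabelsError("training labels must include both classes")
    return X, y


def _objective(theta: np.ndarray, Z: np.ndarray, y: np.ndarray, lam: float):
    """Penalized NLL and gradient; theta = [intercept, weights]."""
    b, w = theta[0], theta[1:]
    z = b + Z @ w
    loss = float(np.sum(_log1p_exp(z) - y * z) + 0.5 * lam * w @ w)
    p = _sigmoid(z)
    r = p - y
    grad = np.empty_like(theta)
    grad[0] = r.sum()
    grad[1:] = Z.T @ r + lam * w
    return loss, grad


def penalized_loss_gradient(
    model: LogisticModel, X: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Objective value and analytic gradient at the model's parameters.

    Exposed so callers can verify first-order optimality of a fit directly.
    """
    X, y = _prepare(X, y)
    Z = model.standardize(X)
    theta = np.concatenate([[model.intercept], model.weights])
    return _objective(theta, Z, y, model.lam)


def train(
    X: np.ndarray,
    y: np.ndarray,
    lam: float = 1.0,
    seed: int | None = None,
    feature_names: list[str] | None = None,
    grad_tol: float = GRAD_TOL,
) -> LogisticModel:
    """Fit the L2 logistic model on raw (unscaled) pair features.

    ``seed`` is accepted for interface uniformity; the optimizer is
    deterministic, so it has no effect on the result.
    """
    X, y = _prepare(X, y)
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(p)]
    if len(feature_names) != p:
        raise ValidationError("feature_names length does not match X")

    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    # constant features (sd at float-noise level) get sd 1 and contribute 0
    # after centering
    const_tol = 1e-12 * np.maximum(1.0, np.abs(mean))
    sd = np.where(sd > const_tol, sd, 1.0)
    Z = (X - mean) / sd

    theta = np.zeros(p + 1)
    res = minimize(
        _objective,
        theta,
        args=(Z, y, lam),
        method="L-BFGS-B",
        jac=True,
        options={"maxiter": 10_000, "ftol": 1e-14, "gtol": 1e-8},
    )
    theta = res.x

    # damped Newton polish: drives the gradient max-norm below grad_tol so
    # refits (e.g. with permuted rows) agree to ~1e-10 in the weights
    for _ in range(MAX_NEWTON_ITER):
        loss, grad = _objective(theta, Z, y, lam)
        if np.max(np.abs(grad)) < grad_tol:
            break
        z = theta[0] + Z @ theta[1:]
        pvec = _sigmoid(z)
        wts = pvec * (1 - pvec)
        Zb = np.concatenate([np.ones((n, 1)), Z], axis=1)
        H = (Zb * wts[:, None]).T @ Zb
        H[1:, 1:] += lam * np.eye(p)
        H[np.diag_indices_from(H)] += 1e-12
        step = cho_solve(cho_factor(H), grad)
        t = 1.0
        while t > 1e-10:
            cand = theta - t * step
            if _objective(cand, Z, y, lam)[0] <= loss:
                theta = cand
                break
            t /= 2
        else:
            break

    return LogisticModel(
        weights=theta[1:].copy(),
        intercept=float(theta[0]),
        lam=float(lam),
        scaler_mean=mean,
        scaler_sd=sd,
        feature_names=list(feature_names),
    )


def predict_proba(model: LogisticModel, X: np.ndarray) -> np.ndarray:
    """Interaction probability for each feature row, in (0, 1)."""
    p = _sigmoid(model.decision_scores(np.asarray(X, dtype=float)))
    # keep strictly inside (0, 1) so log-loss and thresholds stay finite
    eps = np.finfo(float).tiny
    return np.clip(p, eps, 1 - eps)


# ---------------------------------------------------------------------------
# plain-text model serialization
# ---------------------------------------------------------------------------


def save_model(model: LogisticModel, path: str | Path) -> None:
    """Write a versioned plain-text model file.

    Layout: a version line, scalar key-value lines, then one line per feature
    with name, scaler mean, scaler sd and weight (full float64 precision), so
    the format is readable from any language.
    """
    with open(Path(path), "w", encoding="utf-8") as fh:
        fh.write(f"ddicpi-logistic-model version {MODEL_FORMAT_VERSION}\n")
        fh.write(f"lambda {model.lam!r}\n")
        fh.write(f"intercept {model.intercept!r}\n")
        fh.write(f"n_features {len(model.feature_names)}\n")
        fh.write("feature\tmean\tsd\tweight\n")
        for name, m, s, w in zip(
            model.feature_names, model.scaler_mean, model.scaler_sd, model.weights
        ):
            fh.write(f"{name}\t{float(m)!r}\t{float(s)!r}\t{float(w)!r}\n")


def load_model(path: str | Path) -> LogisticModel:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    try:
        magic = lines[0].split()
        if magic[0] != "ddicpi-logistic-model" or magic[1] != "version":
            raise ModelFileError(f"{path}: not a ddicpi model file")
        version = int(magic[2])
        if version != MODEL_FORMAT_VERSION:
            raise ModelFileError(
                f"{path}: unsupported model version {version}"
            )
        scalars: dict[str, str] = {}
        i = 1
        while "\t" not in lines[i]:
            k, v = lines[i].split(maxsplit=1)
            scalars[k] = v
            i += 1
        if lines[i] != "feature\tmean\tsd\tweight":
            raise ModelFileError(f"{path}: missing feature table header")
        n_features = int(scalars["n_features"])
        names, means, sds, weights = [], [], [], []
        for line in lines[i + 1 :]:
            name, m, s, w = line.split("\t")
            names.append(name)
            means.append(float(m))
            sds.append(float(s))
            weights.append(float(w))
        if len(names) != n_features:
            raise ModelFileError(
                f"{path}: truncated file, expected {n_features} features, "
                f"found {len(names)}"
            )
        return LogisticModel(
            weights=np.array(weights),
            intercept=float(scalars["intercept"]),
            lam=float(scalars["lambda"]),
            scaler_mean=np.array(means),
            scaler_sd=np.array(sds),
            feature_names=names,
        )
    except ModelFileError:
        raise
    except (IndexError, KeyError, ValueError) as e:
        raise ModelFileError(f"{path}: corrupted model file ({e})") from None
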