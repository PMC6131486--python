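"""Six regression families behind one fit/predict/persist contract.

The map-reconstruction task is plain supervised regression: given a
flattened patch of concentration curves plus the arterial input function,
predict the value one perfusion parameter takes at the centre voxel.  Six
model families are provided, spanning the bias/variance spectrum:

==============  ==============================================
family          notes
==============  ==============================================
linear          ordinary least squares via QR factorisation
ridge           L2-penalised linear fit (Cholesky solve)
kernel_ridge    ridge in a Gaussian-kernel feature space
svr             epsilon-insensitive SVR with RBF kernel
mlp             feedforward net, 5 hidden layers (7 in total)
random_forest   100 bagged CART regression trees
==============  ==============================================

Features are standardised (zero mean, unit variance, statistics fit on the
training set only) for the scale-sensitive families (ridge, kernel ridge,
SVR, MLP); trees and the plain linear fit see raw features.  Targets are
likewise standardised for SVR and MLP so that the epsilon tube and the
optimiser's step sizes are scale-free; predictions are mapped back.

Every fitted model is deterministic given its seed and serialises to disk
(joblib) with identical reloaded predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import joblib
import numpy as np
from scipy import linalg as sla
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.metrics import pairwise_distances
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

__all__ = [
    "FAMILIES",
    "ModelSpec",
    "FittedModel",
    "fit_linear",
    "fit_ridge",
    "fit_svr",
    "fit_mlp",
    "fit_random_forest",
    "fit_family",
    "predict",
    "save_model",
    "load_model",
    "median_pairwise_sigma",
]

FAMILIES = ("linear", "ridge", "kernel_ridge", "svr", "mlp", "random_forest")

#: default hidden-layer widths; with input and output this is a 7-layer net
DEFAULT_MLP_LAYERS = (256, 128, 64, 32, 16)


@dataclass(frozen=True)
class ModelSpec:
    """A regression family plus its hyperparameters and seed."""

    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")


@dataclass
class FittedModel:
    """A trained regressor with its scalers and provenance."""

    spec: ModelSpec
    state: Any
    x_scaler: StandardScaler | None = None
    y_mean: float = 0.0
    y_scale: float = 1.0
    n_features: int = 0
    training_provenance: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)


def median_pairwise_sigma(X: np.ndarray, max_rows: int = 500, seed: int = 0) -> float:
    """Median pairwise Euclidean distance, the standard RBF width heuristic.

    Subsamples to ``max_rows`` rows for large inputs (deterministic).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] > max_rows:
        idx = np.random.default_rng(seed).choice(X.shape[0], max_rows, replace=False)
        X = X[idx]
    d = pairwise_distances(X)
    med = float(np.median(d[np.triu_indices_from(d, k=1)]))
    return med if med > 0 else 1.0


def _standardise(X: np.ndarray) -> tuple[np.ndarray, StandardScaler]:
    scaler = StandardScaler().fit(X)
    # features that are constant up to floating-point dust (e.g. pre-bolus
    # time points that are identically zero) must not be amplified: treat
    # any scale below a relative floor as unit scale, like exact constants
    floor = max(1e-9 * float(scaler.scale_.max()), 1e-12)
    scaler.scale_ = np.where(scaler.scale_ < floor, 1.0, scaler.scale_)
    return scaler.transform(X), scaler


def _check_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-D (rows, features)")
    if X.shape[0] != y.size:
        raise ValueError("X and y have different numbers of rows")
    return X, y


def fit_linear(X: np.ndarray, y: np.ndarray) -> FittedModel:
    """Ordinary least squares through a QR factorisation (with intercept).

    For full-rank tall problems the unique minimiser of the sum of squared
    residuals; rank-deficient designs fall back to the minimum-norm
    solution (SVD-based lstsq) with a warning.
    """
    import warnings

    X, y = _check_xy(X, y)
    Xa = np.column_stack([np.ones(X.shape[0]), X])
    n, p = Xa.shape
    rank = np.linalg.matrix_rank(Xa) if n < p else None
    if n < p or (rank is not None and rank < p):
        warnings.warn("rank-deficient design: using minimum-norm solution", stacklevel=2)
        beta = np.linalg.lstsq(Xa, y, rcond=None)[0]
    else:
        Q, R = np.linalg.qr(Xa)
        try:
            beta = sla.solve_triangular(R, Q.T @ y)
        except (sla.LinAlgError, ValueError):
            warnings.warn(
                "singular triangular factor: using minimum-norm solution", stacklevel=2
            )
            beta = np.linalg.lstsq(Xa, y, rcond=None)[0]
    return FittedModel(
        spec=ModelSpec("linear"), state=beta, n_features=X.shape[1]
    )


class _GaussianKernelRidgeState:
    """Kernel ridge in the dual: (K + alpha I) a = y solved by Cholesky.

    The kernel Gram matrix is factorised in place (one O(n^2) buffer), so
    training at n ~ 15k stays within a few gigabytes.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, alpha: float, gamma: float):
        self.X_train = X
        self.gamma = gamma
        K = rbf_kernel(X, gamma=gamma)
        K.flat[:: K.shape[0] + 1] += alpha  # K + alpha*I, in place
        factor = sla.cho_factor(K, lower=True, overwrite_a=True, check_finite=False)
        self.dual_coef = sla.cho_solve(factor, y, check_finite=False)
        del K, factor

    def predict(self, X: np.ndarray) -> np.ndarray:
        return rbf_kernel(X, self.X_train, gamma=self.gamma) @ self.dual_coef


def fit_ridge(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 1.0,
    kernel: str = "none",
    sigma: float | None = None,
    seed: int = 0,
) -> FittedModel:
    """Ridge regression, linear or Gaussian-kernel, solved by Cholesky.

    ``kernel='none'`` gives the penalised linear fit; ``kernel='gaussian'``
    gives kernel ridge with an RBF kernel of width ``sigma`` (default: the
    median-pairwise-distance heuristic).  alpha must be positive, which
    guarantees a positive-definite system.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    X, y = _check_xy(X, y)
    Xs, scaler = _standardise(X)
    if kernel == "none":
        state = Ridge(alpha=alpha, solver="cholesky").fit(Xs, y)
        spec = ModelSpec("ridge", {"alpha": alpha})
    elif kernel == "gaussian":
        sig = sigma if sigma is not None else median_pairwise_sigma(Xs, seed=seed)
        # centre targets so the dual fit models deviations from the mean
        y_mean = float(y.mean())
        state = _GaussianKernelRidgeState(Xs, y - y_mean, alpha, gamma=1.0 / (2.0 * sig**2))
        spec = ModelSpec("kernel_ridge", {"alpha": alpha, "sigma": sig}, seed=seed)
        return FittedModel(
            spec=spec, state=state, x_scaler=scaler, y_mean=y_mean, n_features=X.shape[1]
        )
    else:
        raise ValueError("kernel must be 'none' or 'gaussian'")
    return FittedModel(spec=spec, state=state, x_scaler=scaler, n_features=X.shape[1])


def fit_svr(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 10.0,
    epsilon: float = 0.1,
    sigma: float | None = None,
    seed: int = 0,
    max_iter: int = 200_000,
) -> FittedModel:
    """Epsilon-insensitive support-vector regression with an RBF kernel.

    Targets are standardised so epsilon is expressed in target standard
    deviations; the default tube of 0.1 sd keeps the support-vector set
    sparse without measurable accuracy loss on the synthetic benchmark.  ``max_iter`` bounds the SMO iteration count as a runtime
    safeguard on very large problems.
    """
    if C <= 0 or epsilon < 0:
        raise ValueError("C must be > 0 and epsilon >= 0")
    X, y = _check_xy(X, y)
    Xs, scaler = _standardise(X)
    y_mean, y_scale = float(y.mean()), float(y.std()) or 1.0
    ys = (y - y_mean) / y_scale
    sig = sigma if sigma is not None else median_pairwise_sigma(Xs, seed=seed)
    state = SVR(
        C=C,
        epsilon=epsilon,
        gamma=1.0 / (2.0 * sig**2),
        tol=1e-3,
        cache_size=500,
        max_iter=max_iter,
    ).fit(Xs, ys)
    return FittedModel(
        spec=ModelSpec("svr", {"C": C, "epsilon": epsilon, "sigma": sig}, seed=seed),
        state=state,
        x_scaler=scaler,
        y_mean=y_mean,
        y_scale=y_scale,
        n_features=X.shape[1],
    )


def fit_mlp(
    X: np.ndarray,
    y: np.ndarray,
    layers: tuple[int, ...] = DEFAULT_MLP_LAYERS,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
    early_stopping: bool = True,
) -> FittedModel:
    """Feedforward network with tanh hidden units and a linear output.

    The default five hidden layers plus input and output give a
    seven-layer network.  Optimised with Adam (the library's stochastic
    first-order solver; recorded in provenance).  Deterministic given the
    seed.
    """
    X, y = _check_xy(X, y)
    Xs, scaler = _standardise(X)
    y_mean, y_scale = float(y.mean()), float(y.std()) or 1.0
    if float(y.std()) == 0.0:
        # degenerate constant target: nothing to learn, predict the mean
        return FittedModel(
            spec=ModelSpec("mlp", {"layers": tuple(layers), "constant": True}, seed=seed),
            state=None,
            x_scaler=scaler,
            y_mean=y_mean,
            y_scale=1.0,
            n_features=X.shape[1],
        )
    ys = (y - y_mean) / y_scale
    net = MLPRegressor(
        hidden_layer_sizes=tuple(layers),
        activation="tanh",
        solver="adam",
        max_iter=max_iter,
        random_state=seed,
        tol=tol,
        early_stopping=early_stopping,
        n_iter_no_change=10,
        validation_fraction=0.1,
    )
    net.fit(Xs, ys)
    if not np.isfinite(net.loss_):
        raise RuntimeError(f"MLP training diverged: loss={net.loss_!r}")
    return FittedModel(
        spec=ModelSpec("mlp", {"layers": tuple(layers), "solver": "adam"}, seed=seed),
        state=net,
        x_scaler=scaler,
        y_mean=y_mean,
        y_scale=y_scale,
        n_features=X.shape[1],
    )


def fit_random_forest(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 100,
    min_leaf: int = 5,
    seed: int = 0,
    max_features: str | float = "sqrt",
) -> FittedModel:
    """Bagged CART regression trees; prediction is the mean over trees.

    Trees grow on bootstrap resamples until leaves reach ``min_leaf``
    samples; each split considers a random feature subset (default sqrt,
    the canonical random-forest choice; set 1.0 for pure bagging).
    """
    if n_trees < 1 or min_leaf < 1:
        raise ValueError("n_trees and min_leaf must be >= 1")
    X, y = _check_xy(X, y)
    if X.shape[0] < min_leaf:
        raise ValueError(f"need at least min_leaf={min_leaf} rows, got {X.shape[0]}")
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        min_samples_leaf=min_leaf,
        max_features=max_features,
        random_state=seed,
        n_jobs=1,
    ).fit(X, y)
    return FittedModel(
        spec=ModelSpec(
            "random_forest",
            {"n_trees": n_trees, "min_leaf": min_leaf, "max_features": max_features},
            seed=seed,
        ),
        state=forest,
        n_features=X.shape[1],
    )


def fit_family(family: str, X: np.ndarray, y: np.ndarray, seed: int = 0, **hp) -> FittedModel:
    """Dispatch to the named family's fit function."""
    if family == "linear":
        return fit_linear(X, y)
    if family == "ridge":
        return fit_ridge(X, y, seed=seed, **hp)
    if family == "kernel_ridge":
        return fit_ridge(X, y, kernel="gaussian", seed=seed, **hp)
    if family == "svr":
        return fit_svr(X, y, seed=seed, **hp)
    if family == "mlp":
        return fit_mlp(X, y, seed=seed, **hp)
    if family == "random_forest":
        return fit_random_forest(X, y, seed=seed, **hp)
    raise ValueError(f"unknown family {family!r}")


def predict(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """One finite prediction per row; a pure function of (model, X)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (rows, features)")
    if X.shape[0] == 0:
        return np.empty(0)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature width mismatch: model expects {model.n_features}, got {X.shape[1]}"
        )
    if model.spec.family == "linear":
        beta = model.state
        out = beta[0] + X @ beta[1:]
    elif model.state is None:  # degenerate constant-target model
        out = np.full(X.shape[0], model.y_mean)
    else:
        Xs = model.x_scaler.transform(X) if model.x_scaler is not None else X
        out = np.asarray(model.state.predict(Xs), dtype=float)
        out = out * model.y_scale + model.y_mean
    if not np.all(np.isfinite(out)):
        raise RuntimeError("non-finite predictions")
    return out


def save_model(model: FittedModel, path) -> None:
    joblib.dump({"format_version": 1, "model": model}, path)


def load_model(path) -> FittedModel:
    payload = joblib.load(path)
    if payload.get("format_version") != 1:
        raise ValueError("unrecognised model artifact version")
    return payload["model"]
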