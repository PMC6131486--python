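"""Accuracy metrics and the sample-size / patch-size experiment drivers.

Two complementary error summaries are used throughout:

* NRMSE — root-mean-square error normalised by the range of the reference
  values, so errors are comparable across parameters with different units;
* the coefficient of repeatability CR = 1.96 * RMSE, the half-width of the
  interval expected to contain 95% of prediction-reference differences
  (the limits of agreement of a Bland-Altman analysis centred at zero).

Model selection experiments operate at the *case* (patient) level: the
train/test split assigns whole cases to one side, so no voxel of a test
case can leak into training.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import regressors
from .features import build_dataset, patch_feature_length

__all__ = [
    "rmse",
    "nrmse",
    "coefficient_of_repeatability",
    "bland_altman",
    "split_cases",
    "evaluate_model",
    "sample_size_experiment",
    "patch_size_experiment",
    "bootstrap_nrmse_difference",
]


def _pair(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError("y and yhat have different lengths")
    return y, yhat


def rmse(y, yhat) -> float:
    """Root-mean-square prediction error."""
    y, yhat = _pair(y, yhat)
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def nrmse(y, yhat) -> float:
    """RMSE divided by the range of the reference values y.

    Raises on constant y (zero range).
    """
    y, yhat = _pair(y, yhat)
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    rng = float(y.max() - y.min())
    if rng == 0:
        raise ValueError("reference values are constant: NRMSE undefined")
    return rmse(y, yhat) / rng

def coefficient_of_repeatability(y, yhat) -> float:
    """CR = 1.96 * sqrt(mean squared difference)."""
    return 1.96 * rmse(y, yhat)


def bland_altman(y, yhat) -> np.ndarray:
    """Per-sample (pair mean, difference) points.

    Returns an (n, 2) array of ((yhat + y)/2, yhat - y) — the conventional
    Bland-Altman coordinates (mean on the abscissa, difference on the
    ordinate).
    """
    y, yhat = _pair(y, yhat)
    return np.column_stack([(yhat + y) / 2.0, yhat - y])


def split_cases(
    case_ids: list, train_fraction: float = 0.8, seed: int = 0
) -> tuple[list, list]:
    """Random case-level split: disjoint, exhaustive, seeded."""
    ids = list(case_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 cases to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n_train = int(round(train_fraction * len(ids)))
    if n_train == 0 or n_train == len(ids):
        raise ValueError(
            f"train_fraction={train_fraction} leaves one side of the split empty"
        )
    perm = np.random.default_rng(seed).permutation(len(ids))
    train = [ids[i] for i in sorted(perm[:n_train])]
    test = [ids[i] for i in sorted(perm[n_train:])]
    return train, test


def evaluate_model(model, X_test, y_test) -> dict:
    """NRMSE, RMSE and CR of a fitted model on held-out rows."""
    yhat = regressors.predict(model, X_test)
    return {
        "nrmse": nrmse(y_test, yhat),
        "rmse": rmse(y_test, yhat),
        "cr": coefficient_of_repeatability(y_test, yhat),
        "n": int(np.asarray(y_test).size),
    }


def default_size_grid(lo: int = 100, hi: int = 16_000, n_points: int = 8) -> list[int]:
    """Geometrically spaced sample-size grid (the experiment default)."""
    return [int(round(v)) for v in np.geomspace(lo, hi, n_points)]


def sample_size_experiment(
    train_cases: list,
    test_cases: list,
    families: list[str],
    parameter: str,
    sizes: list[int] | None = None,
    e: int = 0,
    seed: int = 0,
    n_test: int = 2000,
    family_hyperparameters: dict | None = None,
) -> pd.DataFrame:
    """Error versus number of training samples, per family.

    A single training pool of ``max(sizes)`` rows is drawn once and
    shuffled; each size trains on the *prefix* of that pool (so smaller
    training sets are nested in larger ones) and is scored on one fixed
    test set drawn from held-out cases.  Returns a tidy table with one row
    per family x size.
    """
    sizes = sorted(sizes) if sizes else default_size_grid()
    hp = family_hyperparameters or {}
    pool = build_dataset(
        train_cases, parameter, e=e, n_samples=sizes[-1], seed=seed
    )
    if len(pool) < sizes[-1]:
        raise ValueError(
            f"training pool has {len(pool)} rows; largest size {sizes[-1]} unavailable"
        )
    order = np.random.default_rng(seed + 1).permutation(len(pool))
    Xp, yp = pool.features[order], pool.targets[order]
    test = build_dataset(test_cases, parameter, e=e, n_samples=n_test, seed=seed + 2)

    rows = []
    for family in families:
        for size in sizes:
            model = regressors.fit_family(
                family, Xp[:size], yp[:size], seed=seed, **hp.get(family, {})
            )
            res = evaluate_model(model, test.features, test.targets)
            rows.append(
                {
                    "family": family,
                    "parameter": parameter,
                    "e": e,
                    "n_train": size,
                    "seed": seed,
                    "nrmse": res["nrmse"],
                    "cr": res["cr"],
                    "n_test": res["n"],
                }
            )
    return pd.DataFrame(rows)


def patch_size_experiment(
    train_cases: list,
    test_cases: list,
    families: list[str],
    parameter: str,
    e_values: list[int] | None = None,
    n_samples: int = 15_000,
    seed: int = 0,
    n_test: int = 2000,
    family_hyperparameters: dict | None = None,
) -> pd.DataFrame:
    """Error versus in-plane patch size at a fixed training-set size.

    ``e_values`` are half-widths (0..8 covers windows 1x1 through 17x17).
    """
    e_values = list(e_values) if e_values is not None else list(range(9))
    if any(e < 0 for e in e_values):
        raise ValueError("half-widths must be >= 0")
    hp = family_hyperparameters or {}
    rows = []
    for e in e_values:
        train = build_dataset(train_cases, parameter, e=e, n_samples=n_samples, seed=seed)
        test = build_dataset(test_cases, parameter, e=e, n_samples=n_test, seed=seed + 2)
        expected_width = patch_feature_length(e, train.provenance["n_time"])
        assert train.features.shape[1] == expected_width
        for family in families:
            model = regressors.fit_family(
                family, train.features, train.targets, seed=seed, **hp.get(family, {})
            )
            res = evaluate_model(model, test.features, test.targets)
            rows.append(
                {
                    "family": family,
                    "parameter": parameter,
                    "e": e,
                    "window": 2 * e + 1,
                    "n_train": len(train),
                    "seed": seed,
                    "nrmse": res["nrmse"],
                    "cr": res["cr"],
                    "n_test": res["n"],
                }
            )
    return pd.DataFrame(rows)


def bootstrap_nrmse_difference(
    y: np.ndarray,
    yhat_a: np.ndarray,
    yhat_b: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
) -> dict:
    """Paired bootstrap comparison of two predictors' NRMSE on shared y.

    Resamples test rows with replacement and reports the mean difference
    NRMSE(a) - NRMSE(b), a 95% percentile interval, and the fraction of
    resamples where a improves on b.
    """
    y, a = _pair(y, yhat_a)
    _, b = _pair(y, yhat_b)
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    n = y.size
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        diffs[i] = nrmse(y[idx], a[idx]) - nrmse(y[idx], b[idx])
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return {
        "mean_diff": float(diffs.mean()),
        "ci95": (float(lo), float(hi)),
        "frac_a_better": float(np.mean(diffs < 0)),
    }
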