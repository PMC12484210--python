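"""Ridge tuning-parameter selection by repeated k-fold cross-validation.

For every candidate penalty the model is refit on each training fold
(standardization parameters are learned on the training rows only), held-out
component scores are formed with the training weights, and the out-of-fold
loss is the sum of squared structural-equation residuals on the held-out
samples.  The loss covers the structural part only, matching the scope of the
ridge penalty.  The default protocol is 10 independent repetitions of 5-fold
cross-validation; ties are broken toward the larger (more conservative)
penalty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .core_data import DegenerateVariableError, standardize
from .gsca_engine import EstimationConfig, als_fit, compute_components
from .model_spec import PathModel

__all__ = ["CVConfig", "CVResult", "select_lambda", "default_lambda_grid"]


def default_lambda_grid(n_points: int = 41, upper: float = 1000.0) -> list[float]:
    """0 plus log-spaced candidate penalties on (0, upper]."""
    return [0.0] + list(np.geomspace(1.0, upper, n_points - 1))


@dataclass(frozen=True)
class CVConfig:
    lambda_grid: tuple[float, ...] = tuple(default_lambda_grid())
    n_folds: int = 5
    n_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not self.lambda_grid:
            raise ValueError("lambda_grid must be non-empty")
        if any(l < 0 for l in self.lambda_grid):
            raise ValueError("lambda values must be non-negative")
        if list(self.lambda_grid) != sorted(self.lambda_grid):
            raise ValueError("lambda_grid must be sorted ascending")


@dataclass
class CVResult:
    """Per-candidate out-of-fold error curve and the selected penalty."""

    curve: pd.DataFrame  # columns: lambda, mean_error, sd_error
    selected_lambda: float

    def to_tsv(self, path) -> None:
        self.curve.to_csv(path, sep="\t", index=False)


def _partition(n: int, n_folds: int, seed: int):
    return list(KFold(n_splits=n_folds, shuffle=True, random_state=seed).split(np.arange(n)))


def select_lambda(
    table: pd.DataFrame,
    model: PathModel,
    config: CVConfig | None = None,
    est_config: EstimationConfig | None = None,
) -> CVResult:
    """Select the ridge penalty minimizing mean out-of-fold structural error.

    ``table`` is the raw (unstandardized) indicator table; standardization is
    learned per training fold.  Within each fold the candidates are fit in
    ascending order with warm-started weights, which is fast and keeps the
    procedure deterministic for a given seed.
    """
    cfg = config or CVConfig()
    est = est_config or EstimationConfig()
    X = table.loc[:, model.indicator_names]
    n = len(X)
    if n < 2 * cfg.n_folds:
        raise ValueError(f"need at least {2 * cfg.n_folds} samples for {cfg.n_folds}-fold CV")

    grid = list(cfg.lambda_grid)
    endo = model.endogenous()
    # per-repeat total out-of-fold error for each lambda
    errors = np.zeros((cfg.n_repeats, len(grid)))

    for rep in range(cfg.n_repeats):
        seed = (cfg.seed + rep) % (2**31 - 1)
        folds = _partition(n, cfg.n_folds, seed)
        # resample the partition if a training fold has a constant column
        for attempt in range(20):
            bad = False
            for tr, _ in folds:
                if (X.iloc[tr].std(ddof=0) == 0).any():
                    bad = True
                    break
            if not bad:
                break
            warnings.warn(
                "fold with a constant indicator column; resampling partition",
                RuntimeWarning,
                stacklevel=2,
            )
            seed = (seed + 7919) % (2**31 - 1)
            folds = _partition(n, cfg.n_folds, seed)
        else:
            raise DegenerateVariableError(
                "could not build folds without constant indicator columns"
            )

        for tr, te in folds:
            Xtr = X.iloc[tr]
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0, ddof=0)
            Ztr = (Xtr - mu) / sd
            Zte = (X.iloc[te] - mu) / sd
            warm = None
            for gi, lam in enumerate(grid):
                cfg_fit = EstimationConfig(
                    ridge_lambda=lam,
                    max_iterations=est.max_iterations,
                    convergence_tolerance=est.convergence_tolerance,
                    init_mode=est.init_mode,
                    seed=est.seed,
                )
                fit = als_fit(Ztr, model, cfg_fit, init_weights=warm)
                warm = fit.weights
                Gte = compute_components(
                    Zte, fit.weights, model,
                    interaction_center=fit.interaction_center,
                ).to_numpy()
                eidx = [fit.construct_names.index(e) for e in endo]
                resid = Gte[:, eidx] - Gte @ fit.paths[:, eidx]
                errors[rep, gi] += float(np.sum(resid * resid))

    mean_err = errors.mean(axis=0)
    sd_err = errors.std(axis=0, ddof=1) if cfg.n_repeats > 1 else np.zeros(len(grid))
    best = mean_err.min()
    # ties broken toward the larger penalty
    selected = max(lam for lam, e in zip(grid, mean_err) if e == best)
    curve = pd.DataFrame({"lambda": grid, "mean_error": mean_err, "sd_error": sd_err})
    return CVResult(curve=curve, selected_lambda=float(selected))
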