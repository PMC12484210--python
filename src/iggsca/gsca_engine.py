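"""Alternating-least-squares estimation for component-based path models.

Each construct is represented by a component: a weighted composite of its own
standardized indicators, rescaled to unit (population) variance.  Interaction
constructs carry no indicators; their scores are the standardized element-wise
product of the two parent component scores and are recomputed deterministically
after every weight update.

The fitting criterion is the sum of squared residuals of all indicator
equations (each indicator regressed on its own component) and all structural
equations (each endogenous component regressed on its predictors' components),
plus a ridge penalty ``lambda * sum(b^2)`` on the structural coefficients only;
loadings and weights are never penalized.  The two alternating steps are:

* A-step - given component scores, update loadings by per-construct least
  squares and each endogenous construct's incoming paths by ridge regression;
* W-step - given loadings and paths, update each composite's weight vector by
  least squares against every criterion term its score enters (its indicator
  block, its own structural equation, and all equations where it predicts),
  then renormalize the score to unit variance and recompute interaction scores.

Both sub-steps solve their subproblem exactly, so with interaction scores held
fixed the criterion is non-increasing across iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .model_spec import PathModel

__all__ = [
    "EstimationConfig",
    "ParameterSet",
    "DegenerateComponentError",
    "NonConvergenceWarning",
    "compute_components",
    "als_fit",
    "r_squared",
]


class DegenerateComponentError(ValueError):
    """A composite collapsed to zero variance (e.g. all-zero weights)."""


class NonConvergenceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class EstimationConfig:
    ridge_lambda: float = 0.0
    max_iterations: int = 500
    convergence_tolerance: float = 1e-6
    init_mode: str = "equal_weights"  # or "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be non-negative")
        if self.convergence_tolerance <= 0:
            raise ValueError("convergence_tolerance must be positive")
        if self.init_mode not in ("equal_weights", "random"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")


class _Compiled:
    """Index arrays binding a PathModel to a fixed indicator column order."""

    def __init__(self, model: PathModel, columns: Sequence[str]):
        col_of = {c: i for i, c in enumerate(columns)}
        missing = [i for i in model.indicator_names if i not in col_of]
        if missing:
            raise ValueError(f"indicator columns missing from data: {missing[:5]}")
        self.model = model
        self.names = model.construct_names
        self.index = {n: j for j, n in enumerate(self.names)}
        self.kinds = [c.kind for c in model.constructs]
        self.ind_cols = [
            np.array([col_of[i] for i in c.indicators], dtype=int)
            for c in model.constructs
        ]
        # free weights: composites with >= 2 indicators; single-indicator
        # constructs have weight = loading = 1 fixed
        self.free = [
            c.kind != "interaction" and len(c.indicators) >= 2
            for c in model.constructs
        ]
        self.inter = [
            (self.index[c.name], self.index[c.parents[0]], self.index[c.parents[1]])
            for c in model.constructs
            if c.kind == "interaction"
        ]
        self.n_constructs = len(self.names)
        endo = model.endogenous()
        self.endo_idx = np.array([self.index[n] for n in endo], dtype=int)
        self.parents = [
            np.array([self.index[a] for a, b in model.edges if b == n], dtype=int)
            for n in endo
        ]
        self.bmask = np.zeros((self.n_constructs, self.n_constructs), dtype=bool)
        for a, b in model.edges:
            self.bmask[self.index[a], self.index[b]] = True


@dataclass
class ParameterSet:
    """Estimated weights, loadings, structural paths, scores and diagnostics."""

    model: PathModel
    indicator_names: list[str]
    construct_names: list[str]
    weights: np.ndarray       # p x c, nonzero only within own blocks
    loadings: np.ndarray      # c x p, nonzero only for own indicators
    paths: np.ndarray         # c x c, nonzero only on model edges
    scores: np.ndarray        # n x c, unit population variance per column
    r2: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    criterion_trace: list[float] = field(default_factory=list)
    converged: bool = True
    n_iterations: int = 0
    ridge_lambda: float = 0.0
    interaction_center: dict[str, tuple[float, float]] = field(default_factory=dict)

    # -- tidy accessors -----------------------------------------------------

    def path_series(self) -> pd.Series:
        """Structural coefficients as a Series indexed by (source, target)."""
        idx = {n: j for j, n in enumerate(self.construct_names)}
        data = {(a, b): self.paths[idx[a], idx[b]] for a, b in self.model.edges}
        s = pd.Series(data, dtype=float)
        s.index.names = ["source", "target"]
        return s

    def loading_series(self) -> pd.Series:
        """Loadings as a Series indexed by (construct, indicator)."""
        cidx = {n: j for j, n in enumerate(self.construct_names)}
        iidx = {n: j for j, n in enumerate(self.indicator_names)}
        data = {
            (c.name, ind): self.loadings[cidx[c.name], iidx[ind]]
            for c in self.model.constructs
            for ind in c.indicators
        }
        s = pd.Series(data, dtype=float)
        s.index.names = ["construct", "indicator"]
        return s

    def weight_series(self) -> pd.Series:
        cidx = {n: j for j, n in enumerate(self.construct_names)}
        iidx = {n: j for j, n in enumerate(self.indicator_names)}
        data = {
            (c.name, ind): self.weights[iidx[ind], cidx[c.name]]
            for c in self.model.constructs
            for ind in c.indicators
        }
        s = pd.Series(data, dtype=float)
        s.index.names = ["construct", "indicator"]
        return s

    def score_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, columns=self.construct_names)


# ---------------------------------------------------------------------------


def _as_matrix(Z, model: PathModel) -> tuple[np.ndarray, list[str]]:
    names = model.indicator_names
    if isinstance(Z, pd.DataFrame):
        return Z.loc[:, names].to_numpy(dtype=float), names
    Z = np.asarray(Z, dtype=float)
    if Z.shape[1] != len(names):
        raise ValueError(
            f"indicator matrix has {Z.shape[1]} columns, model defines {len(names)}"
        )
    return Z, list(names)


def _score_from_weights(Zj: np.ndarray, w: np.ndarray, name: str) -> tuple[np.ndarray, np.ndarray]:
    """Composite score rescaled to unit population variance; returns (score, w_scaled)."""
    s = Zj @ w
    sd = s.std()
    if sd <= 1e-12:
        raise DegenerateComponentError(f"composite {name!r} has zero-variance score")
    return s / sd, w / sd


def compute_components(
    Z, weights: np.ndarray, model: PathModel,
    interaction_center: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Component scores from an indicator matrix and a weight matrix.

    Composite scores are weighted sums of own indicators rescaled to unit
    population variance; interaction scores are element-wise products of the
    two parent scores, standardized.  If ``interaction_center`` is given
    (mean, sd per interaction, e.g. from a training fit), products are
    centered/scaled with those constants instead of the in-sample moments --
    used for out-of-fold score construction.
    """
    X, names = _as_matrix(Z, model)
    comp = _Compiled(model, names)
    n = X.shape[0]
    G = np.zeros((n, comp.n_constructs))
    for j, c in enumerate(model.constructs):
        if c.kind == "interaction":
            continue
        w = weights[comp.ind_cols[j], j]
        if interaction_center is None:
            G[:, j], _ = _score_from_weights(X[:, comp.ind_cols[j]], w, c.name)
        else:
            # out-of-sample: apply training weights as-is, no re-normalization
            G[:, j] = X[:, comp.ind_cols[j]] @ w
    for j, p1, p2 in comp.inter:
        raw = G[:, p1] * G[:, p2]
        if interaction_center is not None:
            m, s = interaction_center[comp.names[j]]
        else:
            m, s = raw.mean(), raw.std()
        if s <= 1e-12:
            raise DegenerateComponentError(
                f"interaction {comp.names[j]!r} has zero-variance product"
            )
        G[:, j] = (raw - m) / s
    return pd.DataFrame(G, columns=comp.names)


def _ridge_solve(gram_pp: np.ndarray, gram_py: np.ndarray, lam: float) -> np.ndarray:
    """Solve (G'G + lam I) b = G'y; min-norm with a warning if singular at lam=0."""
    if lam == 0:
        evals = np.linalg.eigvalsh(gram_pp)
        if evals[-1] <= 0 or evals[0] / evals[-1] < 1e-12:
            warnings.warn(
                "rank-deficient predictor block at lambda=0; using the "
                "minimum-norm solution (a lambda > 0 would regularize it)",
                RuntimeWarning,
                stacklevel=3,
            )
            return np.linalg.pinv(gram_pp, hermitian=True) @ gram_py
    A = gram_pp + lam * np.eye(gram_pp.shape[0])
    c, low = sla.cho_factor(A, check_finite=False)
    return sla.cho_solve((c, low), gram_py, check_finite=False)


def als_fit(
    Z,
    model: PathModel,
    config: EstimationConfig | None = None,
    init_weights: np.ndarray | None = None,
) -> ParameterSet:
    """Fit weights, loadings and ridge-regularized paths by alternating least squares.

    ``Z`` is the standardized indicator matrix (samples x indicators; DataFrame
    columns are matched to the model by name).  ``init_weights`` (p x c) warm
    starts the weight pattern, e.g. from a full-sample fit when refitting
    bootstrap resamples.
    """
    cfg = config or EstimationConfig()
    X, names = _as_matrix(Z, model)
    comp = _Compiled(model, names)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    c_n = comp.n_constructs
    rng = np.random.default_rng(cfg.seed)

    # ----- initialize weights and scores
    W = np.zeros((p, c_n))
    G = np.zeros((n, c_n))
    for j, cdef in enumerate(model.constructs):
        if cdef.kind == "interaction":
            continue
        cols = comp.ind_cols[j]
        if cfg.init_mode == "random" and comp.free[j] and init_weights is None:
            w0 = rng.standard_normal(len(cols))
        else:
            w0 = np.full(len(cols), 1.0 / np.sqrt(len(cols)))
        if init_weights is not None:
            w_init = init_weights[cols, j]
            if np.linalg.norm(w_init) > 1e-12:
                w0 = w_init
        G[:, j], W[cols, j] = _score_from_weights(X[:, cols], w0, cdef.name)

    inter_center: dict[str, tuple[float, float]] = {}

    def refresh_interactions() -> None:
        for j, p1, p2 in comp.inter:
            raw = G[:, p1] * G[:, p2]
            m, s = raw.mean(), raw.std()
            if s <= 1e-12:
                raise DegenerateComponentError(
                    f"interaction {comp.names[j]!r} has zero-variance product"
                )
            G[:, j] = (raw - m) / s
            inter_center[comp.names[j]] = (float(m), float(s))

    refresh_interactions()

    C = np.zeros((c_n, p))
    B = np.zeros((c_n, c_n))
    lam = cfg.ridge_lambda

    # group endogenous constructs sharing a predictor set: one multi-RHS solve
    groups: dict[tuple[int, ...], list[int]] = {}
    for k_local, k in enumerate(comp.endo_idx):
        groups.setdefault(tuple(comp.parents[k_local]), []).append(k)

    def a_step() -> None:
        # loadings: slope of each indicator on its own unit-variance score
        for j in range(c_n):
            cols = comp.ind_cols[j]
            if cols.size:
                C[j, cols] = G[:, j] @ X[:, cols] / n
        # paths: ridge regression per endogenous construct, batched by parent set
        gram = G.T @ G
        for parents, targets in groups.items():
            pidx = np.array(parents, dtype=int)
            sol = _ridge_solve(gram[np.ix_(pidx, pidx)], gram[np.ix_(pidx, targets)], lam)
            B[:, targets] = 0.0
            B[np.ix_(pidx, targets)] = sol

    def criterion() -> float:
        f = 0.0
        for j in range(c_n):
            cols = comp.ind_cols[j]
            if cols.size:
                E = X[:, cols] - np.outer(G[:, j], C[j, cols])
                f += float(np.sum(E * E))
        pred = G @ B[:, comp.endo_idx]
        E = G[:, comp.endo_idx] - pred
        f += float(np.sum(E * E)) + lam * float(np.sum(B * B))
        return f

    def w_step() -> None:
        pred = G @ B  # n x c; only endogenous columns are nonzero
        for j in range(c_n):
            if not comp.free[j]:
                continue
            cols = comp.ind_cols[j]
            Zj = X[:, cols]
            u = Zj @ C[j, cols]
            if comp.bmask[:, j].any():           # own structural equation
                u = u + pred[:, j]
            ks = np.flatnonzero(comp.bmask[j, :])  # equations where j predicts
            if ks.size:
                resid = G[:, ks] - pred[:, ks]
                u = u + resid @ B[j, ks] + G[:, j] * float(B[j, ks] @ B[j, ks])
            w, *_ = sla.lstsq(Zj, u, check_finite=False)
            g_new, w_scaled = _score_from_weights(Zj, w, comp.names[j])
            delta = g_new - G[:, j]
            G[:, j] = g_new
            W[cols, j] = w_scaled
            pred += np.outer(delta, B[j, :])
        refresh_interactions()

    trace: list[float] = []
    a_step()
    trace.append(criterion())
    converged = False
    it = 0
    for it in range(1, cfg.max_iterations + 1):
        w_step()
        a_step()
        f = criterion()
        trace.append(f)
        denom = abs(trace[-2]) if trace[-2] != 0 else 1.0
        if abs(trace[-2] - f) / denom < cfg.convergence_tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"ALS did not converge in {cfg.max_iterations} iterations "
            f"(last relative change {abs(trace[-2] - trace[-1]) / max(abs(trace[-2]), 1e-300):.2e})",
            NonConvergenceWarning,
            stacklevel=2,
        )

    _apply_sign_convention(comp, W, C, B, G)
    # loadings/paths were refreshed by the last a_step before sign flipping;
    # recompute interaction centering for the final orientation
    for j, p1, p2 in comp.inter:
        raw = G[:, p1] * G[:, p2]
        inter_center[comp.names[j]] = (float(raw.mean()), float(raw.std()))

    pred = G @ B[:, comp.endo_idx]
    resid = G[:, comp.endo_idx] - pred
    r2 = pd.Series(
        1.0 - (resid * resid).sum(axis=0) / n,
        index=[comp.names[k] for k in comp.endo_idx],
        name="r2",
    )

    return ParameterSet(
        model=model,
        indicator_names=names,
        construct_names=comp.names,
        weights=W,
        loadings=C,
        paths=B,
        scores=G,
        r2=r2,
        criterion_trace=trace,
        converged=converged,
        n_iterations=it,
        ridge_lambda=lam,
        interaction_center=inter_center,
    )


def _apply_sign_convention(comp: _Compiled, W, C, B, G) -> None:
    """Orient each free composite so the sum of its loadings is positive.

    Interaction scores flip as the product of their parents' flips; structural
    coefficients are transformed congruently so fitted values are unchanged.
    """
    sign = np.ones(comp.n_constructs)
    for j in range(comp.n_constructs):
        if comp.free[j] and C[j, comp.ind_cols[j]].sum() < 0:
            sign[j] = -1.0
    for j, p1, p2 in comp.inter:
        sign[j] = sign[p1] * sign[p2]
    W *= sign[np.newaxis, :]
    C *= sign[:, np.newaxis]
    G *= sign[np.newaxis, :]
    B *= sign[:, np.newaxis]
    B *= sign[np.newaxis, :]


def r_squared(params: ParameterSet, model: PathModel | None = None) -> pd.Series:
    """Explained-variance fraction per endogenous construct, plus the mean.

    Recomputed from scores and paths: R^2 = 1 - residual SS / n, since every
    component score has unit population variance.  The returned Series carries
    one row per endogenous construct and a trailing "mean" row.
    """
    model = model or params.model
    names = params.construct_names
    idx = {n: j for j, n in enumerate(names)}
    n = params.scores.shape[0]
    out = {}
    for target in model.endogenous():
        k = idx[target]
        resid = params.scores[:, k] - params.scores @ params.paths[:, k]
        out[target] = 1.0 - float(resid @ resid) / n
    s = pd.Series(out, name="r2")
    s.loc["mean"] = s.mean()
    return s
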