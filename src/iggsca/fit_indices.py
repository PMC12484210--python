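"""Overall goodness-of-fit: FIT, GFI and SRMR.

FIT is one minus the ratio of the summed squared residuals of all indicator
and structural equations (the unpenalized fitting criterion) to the total sum
of squares of all indicators and endogenous components; on standardized data
with unit-variance components the denominator is n * (p + n_endogenous).

GFI and SRMR compare the sample indicator covariance matrix S with a
model-reproduced covariance.  For a component model the reproduced matrix is
built by reconstruction: endogenous component scores are replaced by their
structural predictions — recursively, starting from the exogenous components —
and each indicator is reconstructed as loading x (model-implied component
score).  The covariance of the reconstructed indicators is the reproduced
matrix; diagonal entries belonging to single-indicator observed constructs
(and the single-indicator outcome) are set to one since such constructs carry
no measurement residual.  Recommended cutoffs: GFI >= 0.93, SRMR <= 0.08.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gsca_engine import ParameterSet
from .model_spec import PathModel, validate_model

__all__ = [
    "FitIndices",
    "fit_index",
    "reproduced_covariance",
    "gfi_srmr",
    "compute_fit_indices",
    "GFI_CUTOFF",
    "SRMR_CUTOFF",
]

GFI_CUTOFF = 0.93
SRMR_CUTOFF = 0.08


@dataclass(frozen=True)
class FitIndices:
    fit: float
    gfi: float
    srmr: float

    @property
    def gfi_pass(self) -> bool:
        return self.gfi >= GFI_CUTOFF

    @property
    def srmr_pass(self) -> bool:
        return self.srmr <= SRMR_CUTOFF

    def to_dict(self) -> dict:
        return {
            "FIT": self.fit,
            "GFI": self.gfi,
            "SRMR": self.srmr,
            "GFI_cutoff": GFI_CUTOFF,
            "GFI_pass": self.gfi_pass,
            "SRMR_cutoff": SRMR_CUTOFF,
            "SRMR_pass": self.srmr_pass,
        }


def fit_index(Z, params: ParameterSet, model: PathModel | None = None) -> float:
    """FIT: explained fraction of total variance of indicators and components.

    The numerator sums squared residuals of every indicator equation and every
    structural equation at the estimated parameters (the ridge penalty does
    not enter); the denominator is the total sum of squares of all indicators
    plus all endogenous component scores.
    """
    model = model or params.model
    names = params.indicator_names
    X = (Z.loc[:, names].to_numpy(dtype=float)
         if isinstance(Z, pd.DataFrame) else np.asarray(Z, dtype=float))
    n = X.shape[0]
    idx = {nm: j for j, nm in enumerate(params.construct_names)}
    ind_pos = {nm: j for j, nm in enumerate(names)}

    ss_resid = 0.0
    ss_total = float(np.sum(X * X))
    for c in model.constructs:
        if not c.indicators:
            continue
        cols = np.array([ind_pos[i] for i in c.indicators])
        g = params.scores[:, idx[c.name]]
        E = X[:, cols] - np.outer(g, params.loadings[idx[c.name], cols])
        ss_resid += float(np.sum(E * E))
    endo = [idx[t] for t in model.endogenous()]
    resid = params.scores[:, endo] - params.scores @ params.paths[:, endo]
    ss_resid += float(np.sum(resid * resid))
    ss_total += float(np.sum(params.scores[:, endo] ** 2))
    return 1.0 - ss_resid / ss_total


def _implied_scores(params: ParameterSet, model: PathModel) -> np.ndarray:
    """Model-implied component scores: exogenous components keep their estimated
    scores; endogenous components are replaced by structural predictions in
    topological order (recursive substitution)."""
    if validate_model(model):
        raise ValueError("unsupported structure: model must be valid and recursive")
    names = params.construct_names
    idx = {n: j for j, n in enumerate(names)}
    targets = {b for _, b in model.edges}
    implied = params.scores.copy()

    # topological order over endogenous constructs
    remaining = set(targets)
    order: list[str] = []
    while remaining:
        progressed = False
        for t in sorted(remaining):
            if all(p not in remaining for p in (a for a, b in model.edges if b == t)):
                order.append(t)
                remaining.discard(t)
                progressed = True
        if not progressed:  # pragma: no cover - guarded by validate_model
            raise ValueError("unsupported structure: cyclic dependency")
    for t in order:
        implied[:, idx[t]] = implied @ params.paths[:, idx[t]]
    return implied


def reproduced_covariance(
    params: ParameterSet, model: PathModel | None = None
) -> pd.DataFrame:
    """Model-reproduced indicator covariance matrix (population convention)."""
    model = model or params.model
    implied = _implied_scores(params, model)
    names = params.indicator_names
    idx = {n: j for j, n in enumerate(params.construct_names)}
    ind_pos = {nm: j for j, nm in enumerate(names)}
    n = implied.shape[0]

    Zhat = np.zeros((n, len(names)))
    for c in model.constructs:
        for ind in c.indicators:
            j = ind_pos[ind]
            Zhat[:, j] = params.loadings[idx[c.name], j] * implied[:, idx[c.name]]
    Zhat = Zhat - Zhat.mean(axis=0)
    S = Zhat.T @ Zhat / n
    # single-indicator observed/outcome constructs carry no measurement residual
    for c in model.constructs:
        if c.kind in ("observed", "outcome") and len(c.indicators) == 1:
            j = ind_pos[c.indicators[0]]
            S[j, j] = 1.0
    return pd.DataFrame(S, index=names, columns=names)


def gfi_srmr(sample_cov: pd.DataFrame | np.ndarray,
             reproduced_cov: pd.DataFrame | np.ndarray) -> tuple[float, float]:
    """GFI = 1 - tr((S - Sigma)^2)/tr(S^2); SRMR = RMS standardized residual.

    SRMR averages over the lower triangle including the diagonal; residuals
    are standardized by sqrt(s_ii * s_jj) of the sample matrix.
    """
    S = np.asarray(sample_cov, dtype=float)
    R = np.asarray(reproduced_cov, dtype=float)
    if S.shape != R.shape or S.shape[0] != S.shape[1]:
        raise ValueError("covariance matrices must be square and same dimension")
    D = S - R
    gfi = 1.0 - float(np.sum(D * D)) / float(np.sum(S * S))
    d = np.sqrt(np.outer(np.diag(S), np.diag(S)))
    std_resid = D / d
    tril = np.tril_indices(S.shape[0])
    srmr = float(np.sqrt(np.mean(std_resid[tril] ** 2)))
    return gfi, srmr


def compute_fit_indices(Z, params: ParameterSet,
                        model: PathModel | None = None) -> FitIndices:
    """FIT plus GFI/SRMR from the sample vs reproduced indicator covariance."""
    model = model or params.model
    names = params.indicator_names
    X = (Z.loc[:, names].to_numpy(dtype=float)
         if isinstance(Z, pd.DataFrame) else np.asarray(Z, dtype=float))
    Xc = X - X.mean(axis=0)
    S = Xc.T @ Xc / X.shape[0]
    gfi, srmr = gfi_srmr(S, reproduced_covariance(params, model).to_numpy())
    return FitIndices(fit=fit_index(Z, params, model), gfi=gfi, srmr=srmr)
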