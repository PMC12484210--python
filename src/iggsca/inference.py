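"""Bootstrap standard errors, percentile confidence intervals, and indirect effects.

Samples are resampled with replacement and the full model is refit at the
selected ridge penalty for every draw (weights, loadings and paths all refit).
Because component orientation is only identified up to sign, every composite in
a refit is aligned so its score correlates positively with the full-sample
score on the drawn rows before the draw enters the SE/CI computation;
interaction components inherit the product of their parents' signs.
Confidence intervals are plain percentile intervals (2.5/97.5), and an edge is
declared significant when its interval strictly excludes zero — no multiplicity
correction is applied on top of the jointly estimated model.

Indirect (mediation) effects along a chain of paths are products of the
chain's coefficients, with the CI taken from the per-draw products.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import DegenerateVariableError
from .gsca_engine import (
    DegenerateComponentError,
    EstimationConfig,
    ParameterSet,
    als_fit,
)
from .model_spec import PathModel

__all__ = [
    "BootstrapConfig",
    "BootstrapResult",
    "IndirectEffect",
    "bootstrap",
    "significant_paths",
    "indirect_effect",
]


class BootstrapError(RuntimeError):
    pass


@dataclass(frozen=True)
class BootstrapConfig:
    n_resamples: int = 5000
    seed: int = 0
    alignment: str = "score_correlation"

    def __post_init__(self) -> None:
        if self.n_resamples < 2:
            raise ValueError("n_resamples must be >= 2")
        if self.alignment not in ("score_correlation", "none"):
            raise ValueError(f"unknown alignment rule {self.alignment!r}")


@dataclass
class BootstrapResult:
    """Point estimates with bootstrap SEs and percentile 95% CIs.

    ``path_draws`` and ``loading_draws`` retain the per-resample aligned
    parameter vectors so derived quantities (indirect effects) can reuse the
    same draws.
    """

    model: PathModel
    full_fit: ParameterSet
    paths: pd.DataFrame          # index (source, target); estimate, se, ci_low, ci_high
    loadings: pd.DataFrame       # index (construct, indicator); same columns
    path_draws: pd.DataFrame     # n_resamples x edges
    loading_draws: pd.DataFrame  # n_resamples x (construct, indicator)
    n_discarded: int = 0

    @property
    def n_resamples(self) -> int:
        return len(self.path_draws)


def _summarize(point: pd.Series, draws: pd.DataFrame) -> pd.DataFrame:
    se = draws.std(axis=0, ddof=1)
    lo = draws.quantile(0.025, axis=0, interpolation="linear")
    hi = draws.quantile(0.975, axis=0, interpolation="linear")
    return pd.DataFrame(
        {"estimate": point, "se": se, "ci_low": lo, "ci_high": hi}
    )


def _sign_vector(fit_b: ParameterSet, full: ParameterSet, idx: np.ndarray) -> np.ndarray:
    """Per-construct alignment signs: correlate resample scores with the
    full-sample scores restricted to the drawn rows; interactions inherit
    the product of their parents' signs."""
    names = full.construct_names
    pos = {n: j for j, n in enumerate(names)}
    sign = np.ones(len(names))
    for c in full.model.constructs:
        j = pos[c.name]
        if c.kind == "interaction" or len(c.indicators) < 2:
            continue
        dot = float(fit_b.scores[:, j] @ full.scores[idx, j])
        if dot < 0:
            sign[j] = -1.0
    for c in full.model.constructs:
        if c.kind == "interaction":
            j = pos[c.name]
            sign[j] = sign[pos[c.parents[0]]] * sign[pos[c.parents[1]]]
    return sign


def bootstrap(
    table: pd.DataFrame,
    model: PathModel,
    est_config: EstimationConfig | None = None,
    boot_config: BootstrapConfig | None = None,
    full_fit: ParameterSet | None = None,
) -> BootstrapResult:
    """Nonparametric bootstrap of all model parameters.

    ``table`` is the raw (unstandardized) indicator table; each resample is
    restandardized before refitting so the estimates are those the analysis
    would produce on that resample.  Draws where a column or composite
    degenerates (e.g. a SNP constant in the resample) are discarded and
    redrawn; a warning is issued if more than 1% of draws were discarded.
    """
    est = est_config or EstimationConfig()
    cfg = boot_config or BootstrapConfig()
    X = table.loc[:, model.indicator_names]
    n = len(X)
    Xv = X.to_numpy(dtype=float)

    if full_fit is None:
        mu, sd = Xv.mean(axis=0), Xv.std(axis=0)
        if (sd == 0).any():
            raise DegenerateVariableError("constant indicator column in full sample")
        full_fit = als_fit(
            pd.DataFrame((Xv - mu) / sd, columns=X.columns), model, est
        )

    rng = np.random.default_rng(cfg.seed)
    edge_index = pd.MultiIndex.from_tuples(model.edges, names=["source", "target"])
    load_index = full_fit.loading_series().index
    cpos = {nm: j for j, nm in enumerate(full_fit.construct_names)}
    ipos = {nm: j for j, nm in enumerate(full_fit.indicator_names)}
    e_src = np.array([cpos[a] for a, _ in model.edges])
    e_dst = np.array([cpos[b] for _, b in model.edges])
    l_con = np.array([cpos[c] for c, _ in load_index])
    l_ind = np.array([ipos[i] for _, i in load_index])

    path_draws = np.empty((cfg.n_resamples, len(model.edges)))
    load_draws = np.empty((cfg.n_resamples, len(load_index)))
    n_discarded = 0
    max_attempts = cfg.n_resamples * 10 + 100

    b = 0
    attempts = 0
    while b < cfg.n_resamples:
        attempts += 1
        if attempts > max_attempts:
            raise BootstrapError("too many degenerate bootstrap draws")
        idx = rng.integers(0, n, size=n)
        Xb = Xv[idx]
        sd = Xb.std(axis=0)
        if (sd == 0).any():
            n_discarded += 1
            continue
        Zb = (Xb - Xb.mean(axis=0)) / sd
        try:
            fit_b = als_fit(
                pd.DataFrame(Zb, columns=X.columns),
                model,
                est,
                init_weights=full_fit.weights,
            )
        except (DegenerateComponentError, DegenerateVariableError):
            n_discarded += 1
            continue
        if cfg.alignment == "score_correlation":
            sign = _sign_vector(fit_b, full_fit, idx)
            B = fit_b.paths * sign[:, None] * sign[None, :]
            C = fit_b.loadings * sign[:, None]
        else:
            B, C = fit_b.paths, fit_b.loadings
        path_draws[b] = B[e_src, e_dst]
        load_draws[b] = C[l_con, l_ind]
        b += 1

    if n_discarded > 0.01 * cfg.n_resamples:
        warnings.warn(
            f"{n_discarded} degenerate bootstrap draws discarded "
            f"({100 * n_discarded / cfg.n_resamples:.1f}% of requested draws)",
            RuntimeWarning,
            stacklevel=2,
        )

    pd_draws = pd.DataFrame(path_draws, columns=edge_index)
    ld_draws = pd.DataFrame(load_draws, columns=load_index)
    return BootstrapResult(
        model=model,
        full_fit=full_fit,
        paths=_summarize(full_fit.path_series(), pd_draws),
        loadings=_summarize(full_fit.loading_series(), ld_draws),
        path_draws=pd_draws,
        loading_draws=ld_draws,
        n_discarded=n_discarded,
    )


def significant_paths(result: BootstrapResult) -> list[tuple[str, str]]:
    """Edges whose 95% percentile CI strictly excludes zero (unrounded bounds)."""
    tab = result.paths
    keep = (tab["ci_low"] > 0) | (tab["ci_high"] < 0)
    return [tuple(e) for e in tab.index[keep]]


@dataclass
class IndirectEffect:
    """Product of path coefficients along a directed chain, with bootstrap CI."""

    chain: tuple[tuple[str, str], ...]
    estimate: float
    se: float
    ci_low: float
    ci_high: float

    @property
    def significant(self) -> bool:
        return self.ci_low > 0 or self.ci_high < 0


def _normalize_chain(chain, model: PathModel) -> tuple[tuple[str, str], ...]:
    chain = list(chain)
    if chain and isinstance(chain[0], str):  # node list -> edge list
        chain = list(zip(chain[:-1], chain[1:]))
    edges = [tuple(e) for e in chain]
    if not edges:
        raise ValueError("empty chain")
    for (a, b), (c, _) in zip(edges[:-1], edges[1:]):
        if b != c:
            raise ValueError(f"chain is not connected at {b!r} -> {c!r}")
    model_edges = set(model.edges)
    missing = [e for e in edges if e not in model_edges]
    if missing:
        raise ValueError(f"chain edges not in model: {missing}")
    return tuple(edges)


def indirect_effect(chain, result: BootstrapResult) -> IndirectEffect:
    """Indirect effect along a connected chain (e.g. gene -> ROI -> outcome).

    The point estimate is the product of the full-sample direct estimates —
    exactly, by construction — and the SE/CI come from the per-resample
    products of the same aligned draws used for the direct effects.
    """
    edges = _normalize_chain(chain, result.model)
    est = float(np.prod([result.paths.loc[e, "estimate"] for e in edges]))
    prod = np.ones(len(result.path_draws))
    for e in edges:
        prod = prod * result.path_draws[e].to_numpy()
    se = float(np.std(prod, ddof=1))
    lo, hi = np.percentile(prod, [2.5, 97.5])
    return IndirectEffect(chain=edges, estimate=est, se=se,
                          ci_low=float(lo), ci_high=float(hi))
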