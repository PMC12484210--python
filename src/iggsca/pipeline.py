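"""End-to-end orchestration: read -> build model -> tune -> fit -> bootstrap ->
mediation -> fit indices -> report bundle."""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_data import (
    Dataset,
    listwise_exclude,
    load_gene_map,
    load_roi_map,
    read_table,
    standardize,
)
from .fit_indices import FitIndices, compute_fit_indices
from .gsca_engine import EstimationConfig, ParameterSet, als_fit, r_squared
from .inference import (
    BootstrapConfig,
    BootstrapResult,
    bootstrap,
    indirect_effect,
    significant_paths,
)
from .model_spec import OUTCOME, PathModel, build_study_model
from .ridge_tuning import CVConfig, CVResult, select_lambda

__all__ = ["RunConfig", "ReportBundle", "run_study_pipeline", "load_dataset"]

# mediation chains always reported when present in the model
FOCAL_CHAINS = (
    ("HTR3A", "ACgG", OUTCOME),
    ("NR3C1", "CO", OUTCOME),
)


@dataclass
class RunConfig:
    """Pipeline settings; exactly one of fixed_lambda / cv may be active."""

    fixed_lambda: float | None = None
    cv: CVConfig | None = None
    estimation: EstimationConfig = field(default_factory=EstimationConfig)
    bootstrap: BootstrapConfig = field(default_factory=lambda: BootstrapConfig(n_resamples=500))
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if (self.fixed_lambda is None) == (self.cv is None):
            raise ValueError("specify exactly one of fixed_lambda or cv")


@dataclass
class ReportBundle:
    model: PathModel
    params: ParameterSet
    boot: BootstrapResult
    fit_indices: FitIndices
    r2: pd.Series
    significant: list[tuple[str, str]]
    indirect: pd.DataFrame
    cv: CVResult | None
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.boot.loadings.rename_axis(["construct", "indicator"]).to_csv(
            out / "loadings.tsv", sep="\t")
        self.boot.paths.rename_axis(["source", "target"]).to_csv(
            out / "paths.tsv", sep="\t")
        self.r2.rename_axis("construct").to_frame("r2").to_csv(out / "r2.tsv", sep="\t")
        pd.DataFrame(self.significant, columns=["source", "target"]).to_csv(
            out / "significant_paths.tsv", sep="\t", index=False)
        self.indirect.to_csv(out / "indirect_effects.tsv", sep="\t", index=False)
        with open(out / "fit_indices.json", "w", encoding="utf-8") as fh:
            json.dump(self.fit_indices.to_dict(), fh, indent=1)
        if self.cv is not None:
            self.cv.to_tsv(out / "cv_curve.tsv")
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, indent=1)


def load_dataset(genotypes_path, volumes_path, phenotypes_path) -> Dataset:
    """Read the three raw tables and apply listwise exclusion + normalization."""
    return listwise_exclude(
        read_table(genotypes_path), read_table(volumes_path), read_table(phenotypes_path)
    )


def enumerate_mediation_chains(
    model: PathModel, significant: list[tuple[str, str]]
) -> list[tuple[str, str, str]]:
    """Every gene -> ROI -> outcome chain whose two legs are both significant,
    plus the focal chains (always reported when present in the model)."""
    sig = set(significant)
    composites = {
        c.name for c in model.constructs if c.kind == "composite"
    }
    rois = {b for _, b in model.edges if b != OUTCOME and (b, OUTCOME) in model.edges}
    gene_like = composites - rois
    chains = []
    for g in sorted(gene_like):
        for r in sorted(rois):
            if (g, r) in sig and (r, OUTCOME) in sig:
                chains.append((g, r, OUTCOME))
    edges = set(model.edges)
    for chain in FOCAL_CHAINS:
        legs = list(zip(chain[:-1], chain[1:]))
        if all(e in edges for e in legs) and chain not in chains:
            chains.append(chain)
    return chains


def run_study_pipeline(
    dataset: Dataset,
    config: RunConfig,
    model: PathModel | None = None,
) -> ReportBundle:
    """Run the full analysis on a Dataset and return (optionally write) the bundle."""
    if model is None:
        model = build_study_model(load_gene_map(), load_roi_map())
    table = dataset.indicator_table()

    cv_result = None
    if config.cv is not None:
        cv_result = select_lambda(table, model, config.cv, config.estimation)
        lam = cv_result.selected_lambda
    else:
        lam = float(config.fixed_lambda)

    est = EstimationConfig(
        ridge_lambda=lam,
        max_iterations=config.estimation.max_iterations,
        convergence_tolerance=config.estimation.convergence_tolerance,
        init_mode=config.estimation.init_mode,
        seed=config.estimation.seed,
    )
    Z = standardize(table.loc[:, model.indicator_names])
    params = als_fit(Z, model, est)
    boot = bootstrap(table, model, est, config.bootstrap, full_fit=params)
    sig = significant_paths(boot)
    fit = compute_fit_indices(Z, params, model)
    r2 = r_squared(params, model)

    chains = enumerate_mediation_chains(model, sig)
    rows = []
    for chain in chains:
        eff = indirect_effect(chain, boot)
        rows.append(
            {
                "chain": " -> ".join(chain),
                "estimate": eff.estimate,
                "se": eff.se,
                "ci_low": eff.ci_low,
                "ci_high": eff.ci_high,
                "significant": eff.significant,
            }
        )
    indirect = pd.DataFrame(
        rows, columns=["chain", "estimate", "se", "ci_low", "ci_high", "significant"]
    )

    manifest = {
        "iggsca_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "n_samples": dataset.n_samples,
        "n_excluded": dataset.n_excluded,
        "n_constructs": len(model.constructs),
        "n_indicators": len(model.indicator_names),
        "n_paths": len(model.edges),
        "ridge_lambda": lam,
        "lambda_source": "cv" if config.cv is not None else "fixed",
        "estimation_seed": est.seed,
        "bootstrap_seed": config.bootstrap.seed,
        "n_resamples": config.bootstrap.n_resamples,
        "n_bootstrap_discarded": boot.n_discarded,
        "converged": params.converged,
        "n_iterations": params.n_iterations,
        "criterion_final": params.criterion_trace[-1],
        "n_significant_paths": len(sig),
    }
    if config.cv is not None:
        manifest["cv"] = {
            "n_folds": config.cv.n_folds,
            "n_repeats": config.cv.n_repeats,
            "seed": config.cv.seed,
            "grid_size": len(config.cv.lambda_grid),
        }

    bundle = ReportBundle(
        model=model,
        params=params,
        boot=boot,
        fit_indices=fit,
        r2=r2,
        significant=sig,
        indirect=indirect,
        cv=cv_result,
        manifest=manifest,
    )
    if config.output_dir is not None:
        bundle.write(config.output_dir)
    return bundle
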