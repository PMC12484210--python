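"""Synthetic datasets with the statistical structure the analysis assumes.

The generator emulates the study's data layout end to end: SNP dosages whose
genotype-class frequencies match the packaged study frequencies, with SNPs in
the same gene correlated through a latent Gaussian (copula) threshold scheme;
an over-dispersed 0-17 potentially-traumatic-events count; gender/age/AUDIT
covariates; ROI part volumes on the cm^3 scale tied to total brain volume; and
a CAPS-5-scale severity outcome.  Structural effects are planted on the same
mediation layout the analysis fits (genes, PTE, gene-by-PTE interactions and
covariates -> ROI components -> severity), and the generative ground truth is
returned alongside every dataset for parameter-recovery testing.

Construct scores are generated explicitly: each exogenous score is the
standardized equal-weight composite the analysis would ideally recover, each
endogenous score is the planted linear combination of parent scores plus a
Gaussian residual rescaled to unit variance.  ROI part indicators are the
construct score attenuated to the configured indicator loading, with residuals
balanced to sum to zero within each construct so the equal-weight composite of
the indicators reproduces the construct score exactly (no attenuation of
planted paths through the measurement layer).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import Dataset, RoiMap, SnpRecord, gene_to_snps, load_gene_map, load_roi_map
from .model_spec import (
    COVARIATES,
    OUTCOME,
    PTE,
    PathModel,
    build_study_model,
    interaction_name,
)

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "TABLE_PLANTED_PATHS",
    "simulate_genotypes",
    "simulate_dataset",
    "write_input_tables",
]

# default planted structural effects: the study's reported mediation paths;
# every other path in the model is zero
TABLE_PLANTED_PATHS: dict[tuple[str, str], float] = {
    ("HTR3A", "ACgG"): -0.11,
    ("NR3C1", "CO"): 0.09,
    ("CO", "PTSD"): -0.11,
    ("OFuG", "PTSD"): -0.13,
    ("ACgG", "PTSD"): -0.10,
    ("PTE", "PTSD"): 0.35,
}


class SimulationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Generative settings; defaults reproduce the study's data conditions."""

    n_samples: int = 231
    seed: int = 0
    within_gene_ld: float = 0.8        # latent correlation of same-gene SNPs
    indicator_loading: float = 0.9     # target ROI indicator-component correlation
    planted_paths: Mapping[tuple[str, str], float] | None = None  # None -> study defaults
    pte_mean: float = 3.72
    pte_sd: float = 2.47
    severity_mean: float = 28.20
    severity_sd: float = 20.33
    age_mean: float = 46.10
    age_sd: float = 13.49
    audit_mean: float = 3.04
    audit_sd: float = 3.61
    male_fraction: float = 0.325

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise SimulationConfigError("n_samples must be >= 10")
        if not (-1.0 < self.within_gene_ld < 1.0):
            raise SimulationConfigError("within_gene_ld must be in (-1, 1)")
        if not (0.0 < self.indicator_loading < 1.0):
            raise SimulationConfigError("indicator_loading must be in (0, 1)")

    def resolved_paths(self) -> dict[tuple[str, str], float]:
        if self.planted_paths is None:
            return dict(TABLE_PLANTED_PATHS)
        return {tuple(k): float(v) for k, v in dict(self.planted_paths).items()}


@dataclass
class SyntheticTruth:
    """Planted generative parameters emitted alongside every simulated dataset."""

    planted_paths: dict[tuple[str, str], float]
    indicator_loading: float
    within_gene_ld: float
    seed: int
    n_samples: int
    genes: list[str]
    rois: list[str]

    def to_json(self, path) -> None:
        d = {
            "planted_paths": {f"{a}->{b}": v for (a, b), v in self.planted_paths.items()},
            "indicator_loading": self.indicator_loading,
            "within_gene_ld": self.within_gene_ld,
            "seed": self.seed,
            "n_samples": self.n_samples,
            "genes": self.genes,
            "rois": self.rois,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(d, fh, indent=1)


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(
    config: SimConfig,
    gene_map: Mapping[str, SnpRecord] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Dosage table with study genotype-class margins and within-gene correlation.

    SNPs within a gene share a latent equicorrelated Gaussian; dosage classes
    are cut from the latent normal at the quantiles of the cumulative class
    frequencies, so the marginal class frequencies match the study table in
    expectation while same-gene SNPs are positively dependent.  SNPs in
    different genes are independent.
    """
    gene_map = gene_map or load_gene_map()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    genes = gene_to_snps(gene_map)
    n = config.n_samples
    out: dict[str, np.ndarray] = {}
    for gene, snps in genes.items():
        k = len(snps)
        rho = config.within_gene_ld
        lo = -1.0 / (k - 1) + 1e-9 if k > 1 else -1.0
        if rho < lo:
            import warnings

            warnings.warn(
                f"within_gene_ld {rho} infeasible for {k} SNPs; raised to {lo:.3f}",
                RuntimeWarning,
                stacklevel=2,
            )
            rho = lo
        if k == 1:
            lat = rng.standard_normal((n, 1))
        else:
            cov = np.full((k, k), rho)
            np.fill_diagonal(cov, 1.0)
            lat = rng.multivariate_normal(np.zeros(k), cov, size=n, method="cholesky")
        U = stats.norm.cdf(lat)
        for j, rs in enumerate(snps):
            p0, p1, _ = gene_map[rs].genotype_freqs
            dosage = np.where(U[:, j] < p0, 0, np.where(U[:, j] < p0 + p1, 1, 2))
            out[rs] = dosage.astype(int)
    ids = [f"S{i:05d}" for i in range(n)]
    return pd.DataFrame(out, index=pd.Index(ids, name="sample_id"))


# ---------------------------------------------------------------------------
# helper distributions


def _beta_binomial(rng, n_trials: int, mean: float, sd: float, size: int) -> np.ndarray:
    """Over-dispersed count on 0..n_trials matching the target mean and SD."""
    p = mean / n_trials
    base_var = n_trials * p * (1 - p)
    rho = (sd**2 / base_var - 1.0) / (n_trials - 1)
    if rho <= 0:  # no over-dispersion needed
        return rng.binomial(n_trials, p, size=size)
    ab = 1.0 / rho - 1.0
    a, b = p * ab, (1 - p) * ab
    return rng.binomial(n_trials, rng.beta(a, b, size=size))


def _neg_binomial(rng, mean: float, sd: float, size: int) -> np.ndarray:
    var = sd**2
    if var <= mean:
        return rng.poisson(mean, size=size)
    r = mean**2 / (var - mean)
    lam = rng.gamma(shape=r, scale=mean / r, size=size)
    return rng.poisson(lam)


def _std(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def _balanced_residuals(rng, n: int, k: int, var: float) -> np.ndarray:
    """n x k residuals with per-column variance `var` that sum to zero across
    the k columns, so the equal-weight composite is residual-free."""
    if k == 1:
        return np.zeros((n, 1))
    g = rng.standard_normal((n, k))
    d = g - g.mean(axis=1, keepdims=True)
    # Var(d_ij) = var_g * (1 - 1/k); rescale to the requested variance
    return d * np.sqrt(var / (1.0 - 1.0 / k))


# ---------------------------------------------------------------------------
# full dataset


def simulate_dataset(
    config: SimConfig | None = None,
    gene_map: Mapping[str, SnpRecord] | None = None,
    roi_map: RoiMap | None = None,
    model: PathModel | None = None,
) -> tuple[Dataset, SyntheticTruth]:
    """Simulate a complete, missing-free dataset plus its generative truth.

    Passing a reduced ``roi_map`` (e.g. ``load_roi_map().subset([...])``)
    produces a correspondingly reduced dataset/model for fast simulations.
    """
    cfg = config or SimConfig()
    gene_map = gene_map or load_gene_map()
    roi_map = roi_map or load_roi_map()
    model = model or build_study_model(gene_map, roi_map)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    genes = gene_to_snps(gene_map)
    planted = cfg.resolved_paths()
    model_edges = set(model.edges)
    bad = [e for e in planted if e not in model_edges]
    if bad:
        raise SimulationConfigError(f"planted paths not in model: {bad}")

    # --- exogenous observed data
    genotypes = simulate_genotypes(cfg, gene_map, rng)
    pte = _beta_binomial(rng, 17, cfg.pte_mean, cfg.pte_sd, n).astype(int)
    gender = (rng.random(n) < cfg.male_fraction).astype(int)  # 1 = male
    age = rng.normal(cfg.age_mean, cfg.age_sd, n).clip(18, 90)
    audit = np.clip(_neg_binomial(rng, cfg.audit_mean, cfg.audit_sd, n), 0, 40)

    # --- exogenous construct scores: standardized equal-weight composites
    scores: dict[str, np.ndarray] = {}
    for gene, snps in genes.items():
        D = genotypes[snps].to_numpy(dtype=float)
        sd = D.std(axis=0)
        if (sd == 0).any():
            const = [s for s, v in zip(snps, sd) if v == 0]
            raise SimulationConfigError(
                f"SNP(s) {const} constant in simulated sample (n too small "
                "for their minor-allele frequency); increase n_samples"
            )
        scores[gene] = _std(((D - D.mean(axis=0)) / sd).mean(axis=1))
    scores[PTE] = _std(pte.astype(float))
    for cov_name, vals in zip(COVARIATES, (gender, age, audit)):
        scores[cov_name] = _std(vals.astype(float))
    for gene in genes:
        scores[interaction_name(gene)] = _std(scores[gene] * scores[PTE])

    # --- endogenous construct scores: planted effects + scaled residual
    def endo_score(target: str) -> np.ndarray:
        sys = np.zeros(n)
        for (src, dst), b in planted.items():
            if dst == target:
                sys = sys + b * scores[src]
        var_sys = float(sys.var())
        if var_sys > 1.0:
            raise SimulationConfigError(
                f"planted paths into {target!r} imply score variance "
                f"{var_sys:.3f} > 1; shrink the coefficients"
            )
        resid = rng.standard_normal(n) * np.sqrt(1.0 - var_sys)
        return _std(sys + resid)

    for roi in roi_map.rois:
        scores[roi] = endo_score(roi)

    # --- ROI part indicators: attenuated construct score with balanced residuals,
    #     mapped to the cm^3 scale relative to total brain volume
    tbv = rng.normal(roi_map.tbv_mean, roi_map.tbv_sd, n).clip(roi_map.tbv_mean * 0.6)
    L = cfg.indicator_loading
    vol_cols: dict[str, np.ndarray] = {}
    for roi, inds in roi_map.rois.items():
        k = len(inds)
        resid = _balanced_residuals(rng, n, k, 1.0 - L**2)
        base = L * scores[roi] if k > 1 else scores[roi]
        for j, ind in enumerate(inds):
            z = base + resid[:, j]
            mean_rel = ind.mean / roi_map.tbv_mean
            sd_rel = ind.sd / roi_map.tbv_mean
            rel = np.maximum(z * sd_rel + mean_rel, mean_rel / 100.0)
            vol_cols[ind.id] = rel

    # --- outcome on the CAPS-5 scale, truncated at zero
    y_score = endo_score(OUTCOME)
    severity = np.maximum(cfg.severity_mean + cfg.severity_sd * y_score, 0.0)

    ids = genotypes.index
    volumes = pd.DataFrame(vol_cols, index=ids)
    phenotypes = pd.DataFrame(
        {
            "pte": pte,
            "severity": severity,
            "gender": gender,
            "age": age,
            "audit": audit,
        },
        index=ids,
        dtype=float,
    )
    dataset = Dataset(genotypes=genotypes, volumes=volumes, phenotypes=phenotypes)
    truth = SyntheticTruth(
        planted_paths=planted,
        indicator_loading=L,
        within_gene_ld=cfg.within_gene_ld,
        seed=cfg.seed,
        n_samples=n,
        genes=list(genes),
        rois=list(roi_map.rois),
    )
    return dataset, truth


def write_input_tables(
    dataset: Dataset, roi_map: RoiMap, outdir, tbv: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> None:
    """Write the three raw input tables (genotypes, cm^3 volumes with total
    brain volume, phenotypes) a reading pipeline would consume.

    The stored relative volumes are multiplied back onto a per-sample total
    brain volume so that the written table is on the absolute cm^3 scale;
    dividing by the written total reproduces the dataset's relative volumes
    exactly.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n = dataset.n_samples
    if tbv is None:
        rng = rng if rng is not None else np.random.default_rng(0)
        tbv = rng.normal(roi_map.tbv_mean, roi_map.tbv_sd, n).clip(roi_map.tbv_mean * 0.6)
    raw = dataset.volumes.mul(pd.Series(tbv, index=dataset.volumes.index), axis=0)
    raw["total_brain_volume"] = tbv
    dataset.genotypes.to_csv(outdir / "genotypes.csv", index_label="sample_id")
    raw.to_csv(outdir / "volumes.csv", index_label="sample_id")
    dataset.phenotypes.to_csv(outdir / "phenotypes.csv", index_label="sample_id")
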