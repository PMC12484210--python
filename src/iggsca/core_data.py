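"""Domain types, table I/O, genotype coding, volume normalization, standardization.

The analysis operates on a per-sample table joining three parts: SNP minor-allele
dosages (0/1/2), brain ROI part volumes expressed relative to total brain volume,
and phenotype/covariate columns (potentially-traumatic-event count, CAPS-5 PTSD
symptom severity, gender, age, AUDIT).  All downstream estimation works on
standardized columns; standardization uses the population (divide-by-n) variance
convention throughout so that unit-variance component constraints and the
loading-equals-correlation identity hold exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources as _ilres
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SnpRecord",
    "RoiMap",
    "Dataset",
    "GenotypeCodingError",
    "ValidationError",
    "DegenerateVariableError",
    "EmptyDatasetError",
    "load_gene_map",
    "load_roi_map",
    "code_minor_alleles",
    "code_genotype_strings",
    "relative_volumes",
    "listwise_exclude",
    "standardize",
    "read_table",
    "write_table",
]


class GenotypeCodingError(ValueError):
    """Raised when a genotype string cannot be coded against its SNP's alleles."""


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


class DegenerateVariableError(ValueError):
    """Raised when a column is constant and cannot be standardized."""


class EmptyDatasetError(ValueError):
    """Raised when listwise exclusion removes every sample."""


@dataclass(frozen=True)
class SnpRecord:
    """Metadata for one biallelic SNP: its gene, wild genotype and minor allele."""

    rs_id: str
    gene: str
    wild_genotype: str
    minor_allele: str
    genotype_freqs: tuple[float, float, float] = (1.0, 0.0, 0.0)

    @property
    def wild_allele(self) -> str:
        return self.wild_genotype[0]

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset({self.wild_allele, self.minor_allele})


@dataclass(frozen=True)
class RoiIndicator:
    id: str
    mean: float  # cm^3, absolute volume scale
    sd: float


@dataclass(frozen=True)
class RoiMap:
    """Construct -> part-indicator assignment with per-indicator volume scales."""

    rois: dict[str, tuple[RoiIndicator, ...]]
    names: dict[str, str]
    tbv_mean: float
    tbv_sd: float

    @property
    def construct_names(self) -> list[str]:
        return list(self.rois)

    @property
    def indicator_names(self) -> list[str]:
        return [ind.id for inds in self.rois.values() for ind in inds]

    def subset(self, keys: Sequence[str]) -> "RoiMap":
        """Restrict to a subset of ROI constructs (used for reduced models)."""
        missing = [k for k in keys if k not in self.rois]
        if missing:
            raise KeyError(f"unknown ROI constructs: {missing}")
        return RoiMap(
            rois={k: self.rois[k] for k in keys},
            names={k: self.names[k] for k in keys},
            tbv_mean=self.tbv_mean,
            tbv_sd=self.tbv_sd,
        )


PHENOTYPE_COLUMNS = ("pte", "severity", "gender", "age", "audit")
TBV_COLUMN = "total_brain_volume"


def load_gene_map() -> dict[str, SnpRecord]:
    """Packaged Table-style gene -> SNP map as an rs_id -> SnpRecord dict.

    The map covers 9 genes and 18 SNPs; genotype class frequencies are the
    study frequencies (with the inconsistent rs4713916 row renormalized).
    """
    raw = json.loads(_ilres.files("iggsca.resources").joinpath("gene_map.json").read_text())
    out: dict[str, SnpRecord] = {}
    for gene, rs_list in raw["genes"].items():
        for rs in rs_list:
            s = raw["snps"][rs]
            counts = s["genotype_counts"]
            total = sum(counts)
            out[rs] = SnpRecord(
                rs_id=rs,
                gene=gene,
                wild_genotype=s["wild_genotype"],
                minor_allele=s["minor_allele"],
                genotype_freqs=tuple(c / total for c in counts),
            )
    return out


def load_roi_map() -> RoiMap:
    """Packaged 60-construct ROI map with cm^3 means/SDs per part indicator."""
    raw = json.loads(_ilres.files("iggsca.resources").joinpath("roi_map.json").read_text())
    rois = {
        key: tuple(RoiIndicator(d["id"], d["mean"], d["sd"]) for d in spec["indicators"])
        for key, spec in raw["rois"].items()
    }
    names = {key: spec["name"] for key, spec in raw["rois"].items()}
    return RoiMap(
        rois=rois,
        names=names,
        tbv_mean=raw["total_brain_volume"]["mean"],
        tbv_sd=raw["total_brain_volume"]["sd"],
    )


def gene_to_snps(gene_map: Mapping[str, SnpRecord]) -> dict[str, list[str]]:
    """Invert an rs_id->SnpRecord map to gene -> ordered rs_id list."""
    out: dict[str, list[str]] = {}
    for rs, rec in gene_map.items():
        out.setdefault(rec.gene, []).append(rs)
    return out


# ---------------------------------------------------------------------------
# genotype coding


def code_minor_alleles(raw_genotype: str, snp: SnpRecord) -> int:
    """Count minor alleles in a two-letter genotype (0 wild, 1 hetero, 2 mutant).

    Order-insensitive: "AG" and "GA" code identically.
    """
    g = raw_genotype.strip().upper()
    if len(g) != 2:
        raise GenotypeCodingError(f"{snp.rs_id}: genotype {raw_genotype!r} is not two letters")
    bad = [a for a in g if a not in snp.alleles]
    if bad:
        raise GenotypeCodingError(
            f"{snp.rs_id}: allele(s) {bad} not among alleles {sorted(snp.alleles)}"
        )
    return sum(a == snp.minor_allele for a in g)


def code_genotype_strings(
    table: pd.DataFrame, gene_map: Mapping[str, SnpRecord]
) -> pd.DataFrame:
    """Convert a sample x rs_id table of genotype strings to dosage counts."""
    out = {}
    for rs in table.columns:
        if rs not in gene_map:
            raise GenotypeCodingError(f"unknown SNP column {rs!r}")
        snp = gene_map[rs]
        out[rs] = table[rs].map(lambda g, s=snp: code_minor_alleles(g, s))
    return pd.DataFrame(out, index=table.index)


def validate_dosages(table: pd.DataFrame) -> None:
    vals = table.to_numpy()
    if not np.isin(vals[~pd.isna(vals)], [0, 1, 2]).all():
        raise ValidationError("dosage entries must be 0, 1 or 2")


# ---------------------------------------------------------------------------
# volume normalization


def relative_volumes(volumes: pd.DataFrame) -> pd.DataFrame:
    """Divide each part volume by the sample's total brain volume.

    `volumes` must carry a ``total_brain_volume`` column; the returned table is
    dimensionless (each value in (0, 1]) and drops that column.
    """
    if TBV_COLUMN not in volumes.columns:
        raise ValidationError(f"missing {TBV_COLUMN!r} column")
    tbv = volumes[TBV_COLUMN].to_numpy(dtype=float)
    if np.any(~np.isfinite(tbv)) or np.any(tbv <= 0):
        raise ValidationError("total brain volume must be positive and finite")
    parts = volumes.drop(columns=[TBV_COLUMN])
    rel = parts.div(volumes[TBV_COLUMN], axis=0)
    too_big = rel.columns[(rel.max(axis=0) > 1.0)].tolist()
    if too_big:
        raise ValidationError(f"part volume exceeds total brain volume: {too_big}")
    return rel


# ---------------------------------------------------------------------------
# standardization (population convention)


def standardize(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Column-standardize to mean 0, population variance 1 (divide by n).

    Raises DegenerateVariableError naming the first constant column.
    """
    is_df = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float) if is_df else np.asarray(matrix, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # ddof=0: population convention
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        name = matrix.columns[zero[0]] if is_df else int(zero[0])
        raise DegenerateVariableError(f"constant column cannot be standardized: {name!r}")
    Z = (X - mu) / sd
    if is_df:
        return pd.DataFrame(Z, index=matrix.index, columns=matrix.columns)
    return Z


# ---------------------------------------------------------------------------
# dataset assembly


@dataclass
class Dataset:
    """Aligned dosage + relative-volume + phenotype tables with no missing values."""

    genotypes: pd.DataFrame  # samples x rs_ids, int dosages
    volumes: pd.DataFrame    # samples x ROI part indicators, relative (dimensionless)
    phenotypes: pd.DataFrame  # samples x (pte, severity, gender, age, audit)
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if not (self.genotypes.index.equals(self.volumes.index)
                and self.genotypes.index.equals(self.phenotypes.index)):
            raise ValidationError("sample ordering differs between tables")
        for part in (self.genotypes, self.volumes, self.phenotypes):
            if part.isna().any().any():
                raise ValidationError("Dataset parts must be complete (no missing values)")
        validate_dosages(self.genotypes)

    @property
    def n_samples(self) -> int:
        return len(self.genotypes)

    def indicator_table(self) -> pd.DataFrame:
        """Joined raw (unstandardized) indicator table in genotype/volume/phenotype order."""
        return pd.concat([self.genotypes, self.volumes, self.phenotypes], axis=1)


def listwise_exclude(
    genotypes: pd.DataFrame,
    volumes: pd.DataFrame,
    phenotypes: pd.DataFrame,
) -> Dataset:
    """Retain only samples present and complete in all three tables.

    `volumes` is given on the raw cm^3 scale including ``total_brain_volume``;
    relative volumes are computed after exclusion.  The number of excluded
    samples (missing anywhere, or absent from a table) is recorded on the
    returned Dataset.
    """
    ids = genotypes.index.union(volumes.index).union(phenotypes.index)
    keep = genotypes.index.intersection(volumes.index).intersection(phenotypes.index)
    complete = (
        genotypes.loc[keep].notna().all(axis=1)
        & volumes.loc[keep].notna().all(axis=1)
        & phenotypes.loc[keep].notna().all(axis=1)
    )
    keep = keep[complete]
    n_excluded = len(ids) - len(keep)
    if len(keep) == 0:
        raise EmptyDatasetError("no complete samples remain after listwise exclusion")
    return Dataset(
        genotypes=genotypes.loc[keep].astype(int),
        volumes=relative_volumes(volumes.loc[keep]),
        phenotypes=phenotypes.loc[keep].astype(float),
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# delimited-text I/O (first column sample_id, UTF-8)


def read_table(path, sep: str | None = None) -> pd.DataFrame:
    """Read a CSV/TSV table whose first column is sample_id."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep, index_col=0, encoding="utf-8")


def write_table(df: pd.DataFrame, path, sep: str | None = None) -> None:
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df.to_csv(path, sep=sep, index_label="sample_id", encoding="utf-8")
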