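"""Construct definitions and the directed structural path pattern.

The study model links gene components (built from SNP dosages), a
potentially-traumatic-events (PTE) count, gene-by-PTE interaction components
and three covariates (gender, age, AUDIT) to 60 brain ROI components, and the
ROI components plus PTE and covariates to PTSD symptom severity.  Every
predictor set is complete: with 9 genes and 60 ROIs the model carries
(9 + 1 + 9 + 3) x 60 + (60 + 1 + 3) = 1,384 directed paths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core_data import RoiMap, SnpRecord, gene_to_snps

__all__ = [
    "ConstructDef",
    "PathModel",
    "ModelSpecificationError",
    "build_study_model",
    "count_free_paths",
    "validate_model",
    "OUTCOME",
    "PTE",
    "COVARIATES",
]

OUTCOME = "PTSD"
PTE = "PTE"
COVARIATES = ("gender", "age", "AUDIT")

KINDS = ("composite", "interaction", "observed", "outcome")


class ModelSpecificationError(ValueError):
    pass


@dataclass(frozen=True)
class ConstructDef:
    """One construct: a composite with indicators, an indicator-free interaction,
    a single-indicator observed covariate, or the single-indicator outcome."""

    name: str
    kind: str
    indicators: tuple[str, ...] = ()
    parents: tuple[str, str] | None = None  # interaction constructs only

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ModelSpecificationError(f"unknown construct kind {self.kind!r}")
        if self.kind == "interaction":
            if self.indicators or self.parents is None or len(self.parents) != 2:
                raise ModelSpecificationError(
                    f"interaction construct {self.name!r} must have exactly 2 parents "
                    "and no indicators"
                )
        else:
            if not self.indicators:
                raise ModelSpecificationError(
                    f"construct {self.name!r} must have at least one indicator"
                )
            if self.parents is not None:
                raise ModelSpecificationError(
                    f"non-interaction construct {self.name!r} cannot have parents"
                )


@dataclass(frozen=True)
class PathModel:
    """Constructs plus the directed edge set (predictor -> outcome pairs)."""

    constructs: tuple[ConstructDef, ...]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.constructs]
        if len(names) != len(set(names)):
            raise ModelSpecificationError("duplicate construct names")

    @property
    def construct_names(self) -> list[str]:
        return [c.name for c in self.constructs]

    @property
    def indicator_names(self) -> list[str]:
        return [ind for c in self.constructs for ind in c.indicators]

    def construct(self, name: str) -> ConstructDef:
        for c in self.constructs:
            if c.name == name:
                return c
        raise KeyError(name)

    def predecessors(self, name: str) -> list[str]:
        return [a for a, b in self.edges if b == name]

    def endogenous(self) -> list[str]:
        """Constructs with at least one incoming structural path, in declaration order."""
        targets = {b for _, b in self.edges}
        return [c.name for c in self.constructs if c.name in targets]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "constructs": [
                {
                    "name": c.name,
                    "kind": c.kind,
                    "indicators": list(c.indicators),
                    **({"parents": list(c.parents)} if c.parents else {}),
                }
                for c in self.constructs
            ],
            "edges": [list(e) for e in self.edges],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PathModel":
        constructs = tuple(
            ConstructDef(
                name=c["name"],
                kind=c["kind"],
                indicators=tuple(c.get("indicators", ())),
                parents=tuple(c["parents"]) if c.get("parents") else None,
            )
            for c in d["constructs"]
        )
        edges = tuple((a, b) for a, b in d["edges"])
        return cls(constructs=constructs, edges=edges)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PathModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def interaction_name(gene: str) -> str:
    return f"{gene}xPTE"


def build_study_model(
    gene_map: Mapping[str, SnpRecord], roi_map: RoiMap
) -> PathModel:
    """Build the full mediation model from a gene map and an ROI map.

    Edge pattern: {each gene, PTE, each gene-by-PTE interaction, gender, age,
    AUDIT} -> each ROI; {each ROI, PTE, gender, age, AUDIT} -> PTSD severity.
    Genes and interactions have no direct path to the outcome (fully mediated
    by the ROIs).  Works for any map cardinalities; the packaged study maps
    give 9 genes / 18 SNPs and 60 ROIs.
    """
    genes = gene_to_snps(gene_map)
    if not genes or not roi_map.rois:
        raise ModelSpecificationError("gene map and ROI map must be non-empty")

    constructs: list[ConstructDef] = []
    for gene, snps in genes.items():
        constructs.append(ConstructDef(gene, "composite", tuple(snps)))
    constructs.append(ConstructDef(PTE, "observed", ("pte",)))
    for gene in genes:
        constructs.append(ConstructDef(interaction_name(gene), "interaction",
                                       parents=(gene, PTE)))
    for cov, col in zip(COVARIATES, ("gender", "age", "audit")):
        constructs.append(ConstructDef(cov, "observed", (col,)))
    for roi, inds in roi_map.rois.items():
        constructs.append(ConstructDef(roi, "composite", tuple(i.id for i in inds)))
    constructs.append(ConstructDef(OUTCOME, "outcome", ("severity",)))

    roi_predictors = (
        list(genes) + [PTE] + [interaction_name(g) for g in genes] + list(COVARIATES)
    )
    edges: list[tuple[str, str]] = []
    for roi in roi_map.rois:
        edges.extend((p, roi) for p in roi_predictors)
    edges.extend((p, OUTCOME) for p in list(roi_map.rois) + [PTE] + list(COVARIATES))

    model = PathModel(constructs=tuple(constructs), edges=tuple(edges))
    violations = validate_model(model)
    if violations:
        raise ModelSpecificationError("; ".join(violations))
    return model


def count_free_paths(model: PathModel) -> int:
    """Number of free structural path coefficients (= |edges|)."""
    return len(model.edges)


def validate_model(model: PathModel) -> list[str]:
    """Return a list of invariant violations (empty iff the model is valid)."""
    violations: list[str] = []
    names = set(model.construct_names)

    # edges reference defined constructs
    for a, b in model.edges:
        for end in (a, b):
            if end not in names:
                violations.append(f"edge endpoint {end!r} is not a defined construct")

    # no indicator shared between constructs
    seen: dict[str, str] = {}
    for c in model.constructs:
        for ind in c.indicators:
            if ind in seen:
                violations.append(
                    f"indicator {ind!r} shared between {seen[ind]!r} and {c.name!r}"
                )
            seen[ind] = c.name

    # interaction parents exist and are not interactions themselves
    by_name = {c.name: c for c in model.constructs}
    for c in model.constructs:
        if c.kind != "interaction":
            continue
        for p in c.parents or ():
            if p not in by_name:
                violations.append(f"interaction {c.name!r} parent {p!r} undefined")
            elif by_name[p].kind == "interaction":
                violations.append(
                    f"interaction {c.name!r} parent {p!r} is itself an interaction"
                )

    # acyclicity of the edge graph (Kahn's algorithm)
    indeg = {n: 0 for n in names}
    succ: dict[str, list[str]] = {n: [] for n in names}
    for a, b in model.edges:
        if a in indeg and b in indeg:
            indeg[b] += 1
            succ[a].append(b)
    queue = [n for n, d in indeg.items() if d == 0]
    visited = 0
    while queue:
        n = queue.pop()
        visited += 1
        for m in succ[n]:
            indeg[m] -= 1
            if indeg[m] == 0:
                queue.append(m)
    if visited < len(names):
        violations.append("structural edge graph contains a cycle")

    return violations
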