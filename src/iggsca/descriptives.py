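"""Group comparisons and distribution screening.

Two-group comparisons use the Welch (unequal-variance) t statistic, computable
either from raw values or from printed (n, mean, SD) summaries.  Distribution
screening reports sample skewness and plain (non-excess, normal = 3) kurtosis
against the conventional structural-modeling cutoffs |skewness| < 2 and
kurtosis < 7.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import Dataset

__all__ = [
    "GroupSummary",
    "MomentsScreen",
    "UndefinedStatisticError",
    "welch_t_from_summaries",
    "welch_t_raw",
    "moments_screen",
    "describe_dataset",
    "SKEWNESS_CUTOFF",
    "KURTOSIS_CUTOFF",
]

SKEWNESS_CUTOFF = 2.0
KURTOSIS_CUTOFF = 7.0


class UndefinedStatisticError(ValueError):
    pass


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean and sample (ddof=1) standard deviation of one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    @classmethod
    def from_values(cls, values) -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        return cls(n=len(v), mean=float(v.mean()), sd=float(v.std(ddof=1)))


def welch_t_from_summaries(a: GroupSummary, b: GroupSummary) -> tuple[float, float, float]:
    """Welch t, Welch-Satterthwaite df, and two-sided p from group summaries."""
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    se2 = va + vb
    if se2 == 0:
        raise UndefinedStatisticError(
            "both group variances are zero; t statistic undefined"
        )
    t = (a.mean - b.mean) / np.sqrt(se2)
    df = se2**2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_t_raw(a_values, b_values) -> tuple[float, float, float]:
    """Welch test from raw values (identical to the summary form by construction)."""
    return welch_t_from_summaries(
        GroupSummary.from_values(a_values), GroupSummary.from_values(b_values)
    )


@dataclass(frozen=True)
class MomentsScreen:
    skewness: float
    kurtosis: float  # plain convention: normal distribution -> 3

    @property
    def passes(self) -> bool:
        return abs(self.skewness) < SKEWNESS_CUTOFF and self.kurtosis < KURTOSIS_CUTOFF


def moments_screen(column) -> MomentsScreen:
    """Sample skewness and plain kurtosis with pass flag against 2.0 / 7.0."""
    v = np.asarray(column, dtype=float)
    if len(v) < 4:
        raise ValueError("need at least 4 observations")
    if v.std() == 0:
        raise UndefinedStatisticError("zero variance; moments undefined")
    return MomentsScreen(
        skewness=float(stats.skew(v, bias=True)),
        kurtosis=float(stats.kurtosis(v, fisher=False, bias=True)),
    )


def describe_dataset(dataset: Dataset, group: pd.Series | None = None) -> pd.DataFrame:
    """Per-phenotype summary table; optionally with two-group Welch tests.

    ``group`` is a binary label Series aligned to the dataset's samples
    (e.g. diagnostic status).  Without it, overall summaries and the moments
    screen are reported; with it, per-group summaries and Welch t/p columns
    are added.
    """
    ph = dataset.phenotypes
    rows = []
    for col in ph.columns:
        v = ph[col]
        screen = moments_screen(v)
        row = {
            "variable": col,
            "n": len(v),
            "mean": v.mean(),
            "sd": v.std(ddof=1),
            "skewness": screen.skewness,
            "kurtosis": screen.kurtosis,
            "moments_pass": screen.passes,
        }
        if group is not None:
            g = group.loc[ph.index]
            levels = sorted(g.unique())
            if len(levels) != 2:
                raise ValueError("group must have exactly two levels")
            a, b = (v[g == lev] for lev in levels)
            t, df, p = welch_t_raw(a, b)
            row.update(
                {
                    f"mean_{levels[0]}": a.mean(),
                    f"sd_{levels[0]}": a.std(ddof=1),
                    f"mean_{levels[1]}": b.mean(),
                    f"sd_{levels[1]}": b.std(ddof=1),
                    "t": t,
                    "df": df,
                    "p": p,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")
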