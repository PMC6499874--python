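"""Cohort-level statistics for torque studies.

Directional asymmetry of each signed measure is tested with a two-tailed
one-sample t test against zero (no left/right difference); laterality
prevalence is summarised in 2 x 2 frontal-by-occipital configuration
tables; species differences in prevalence use the Pearson chi-squared
two-sample test on the 2 x 2 collapse of interest, *without* continuity
correction; pairwise association between measures uses Pearson's r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .metrics import CONFIGURATIONS, TorqueRecord

__all__ = [
    "TestResult",
    "CohortTable",
    "one_sample_t",
    "chi2_prevalence",
    "pearson_r",
    "prevalence_table",
    "species_comparison",
]

FEATURES = ("petalia", "shift", "bending")

#: Signed per-subject variables available for t tests / correlations.
VARIABLES = (
    "delta_length", "delta_height", "delta_width",
    "petalia_frontal", "petalia_occipital",
    "shift_frontal", "shift_occipital",
    "bending_frontal", "bending_occipital",
)


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    name: str
    statistic: float
    df: float
    p: float
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def one_sample_t(mean: Optional[float] = None, sd: Optional[float] = None,
                 n: Optional[int] = None, *,
                 values: Optional[Sequence[float]] = None,
                 name: str = "one-sample t") -> TestResult:
    """Two-tailed one-sample t test of the mean against zero.

    Accepts either summary statistics ``(mean, sd, n)`` — so published
    cohort summaries can be re-tested — or raw ``values`` (mean and the
    n-1-denominator SD are then computed first).

    t = mean / (sd / sqrt(n)), df = n - 1, p from the t distribution.
    """
    if values is not None:
        v = np.asarray(values, dtype=float)
        n = len(v)
        if n < 2:
            raise ValueError("need at least 2 values")
        mean = float(v.mean())
        sd = float(v.std(ddof=1))
    if mean is None or sd is None or n is None:
        raise ValueError("provide either values or (mean, sd, n)")
    if n < 2:
        raise ValueError("n must be >= 2")
    if sd <= 0:
        raise ValueError("sd must be positive")
    t = mean / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * _sps.t.sf(abs(t), df)
    return TestResult(name=name, statistic=float(t), df=df, p=float(p),
                      inputs={"mean": mean, "sd": sd, "n": n})


def chi2_prevalence(a: int, b: int, c: int, d: int,
                    name: str = "chi-squared 2x2") -> TestResult:
    """Pearson chi-squared on a 2 x 2 count table, no continuity correction.

    Table layout ``[[a, b], [c, d]]`` (rows = groups, columns = outcome);
    the statistic is n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)) with 1 df.
    """
    counts = np.array([a, b, c, d], dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    n = counts.sum()
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("every row and column sum must be positive")
    chi2 = n * (a * d - b * c) ** 2 / float(np.prod(margins, dtype=float))
    p = float(_sps.chi2.sf(chi2, 1))
    return TestResult(name=name, statistic=float(chi2), df=1, p=p,
                      inputs={"table": [[a, b], [c, d]]})


def pearson_r(x: Sequence[float], y: Sequence[float],
              name: str = "Pearson r") -> TestResult:
    """Sample Pearson correlation with its two-tailed p on n - 2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-d with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for constant input")
    res = _sps.pearsonr(x, y)
    return TestResult(name=name, statistic=float(res.statistic),
                      df=len(x) - 2, p=float(res.pvalue),
                      inputs={"n": len(x)})


@dataclass
class CohortTable:
    """A collection of per-subject torque records with group labels."""

    records: list[TorqueRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("cohort is empty")

    def __len__(self) -> int:
        return len(self.records)

    def values(self, variable: str) -> np.ndarray:
        """Per-subject values of one signed variable (see VARIABLES)."""
        if variable.startswith("delta_"):
            return np.array([getattr(r.dimensions, variable) for r in self.records])
        return np.array([getattr(r, variable) for r in self.records])

    def configurations(self, feature: str) -> list[str]:
        return [getattr(r, f"config_{feature}").label for r in self.records]

    def summary(self) -> pd.DataFrame:
        """Mean, SD (n-1) and n of every signed variable."""
        rows = {}
        for var in VARIABLES:
            v = self.values(var)
            rows[var] = {"mean": v.mean(), "sd": v.std(ddof=1), "n": len(v)}
        return pd.DataFrame(rows).T

    def asymmetry_tests(self) -> pd.DataFrame:
        """One-sample t test of every signed variable against zero."""
        rows = []
        for var in VARIABLES:
            res = one_sample_t(values=self.values(var), name=var)
            rows.append({"variable": var, "t": res.statistic,
                         "df": res.df, "p": res.p})
        return pd.DataFrame(rows).set_index("variable")


def prevalence_table(cohort: CohortTable, feature: str) -> pd.DataFrame:
    """Percentage of subjects in each frontal-by-occipital quadrant.

    Rows are the occipital side (LO, RO), columns the frontal side
    (LF, RF); a ``total`` row/column carries the marginals.  Percentages
    are full precision; rounding happens only at serialisation.
    """
    if feature not in FEATURES:
        raise ValueError(f"unknown feature {feature!r}")
    labels = cohort.configurations(feature)
    n = len(labels)
    pct = pd.DataFrame(0.0, index=["LO", "RO", "total"],
                       columns=["LF", "RF", "total"])
    for lab in labels:
        f_side, o_side = lab.split("/")
        pct.loc[o_side, f_side] += 100.0 / n
    pct.loc["total"] = pct.loc[["LO", "RO"]].sum()
    pct["total"] = pct[["LF", "RF"]].sum(axis=1)
    return pct


def _quadrant_count(cohort: CohortTable, feature: str, quadrant: str) -> int:
    """Subjects matching a full quadrant ("RF/LO") or one side ("RO", "LF")."""
    labels = cohort.configurations(feature)
    if "/" in quadrant:
        if quadrant not in CONFIGURATIONS:
            raise ValueError(f"unknown quadrant {quadrant!r}")
        return sum(lab == quadrant for lab in labels)
    if quadrant in ("LF", "RF"):
        return sum(lab.startswith(quadrant) for lab in labels)
    if quadrant in ("LO", "RO"):
        return sum(lab.endswith(quadrant) for lab in labels)
    raise ValueError(f"unknown quadrant {quadrant!r}")


def species_comparison(cohort_a: CohortTable, cohort_b: CohortTable,
                       feature: str, quadrant_of_interest: str) -> TestResult:
    """Chi-squared two-sample test of configuration prevalence.

    Each cohort is collapsed to quadrant-of-interest versus the rest —
    a full quadrant such as "RF/LO", or a single axis side such as "RO"
    (rightward vs leftward occipital bending) — and the resulting 2 x 2
    count table is tested with ``chi2_prevalence``.
    """
    ka = _quadrant_count(cohort_a, feature, quadrant_of_interest)
    kb = _quadrant_count(cohort_b, feature, quadrant_of_interest)
    res = chi2_prevalence(ka, len(cohort_a) - ka, kb, len(cohort_b) - kb,
                          name=f"{feature} {quadrant_of_interest} vs rest")
    return res
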