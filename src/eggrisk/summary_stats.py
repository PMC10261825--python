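"""Descriptive statistics, rank correlation and compliance screening.

Summaries follow the reporting convention mean ± SE (standard error of the
mean, SD/sqrt(n) with the n-1 SD) together with min, max and range.
Censored records enter every statistic with their LOQ/2 substitute.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
from scipy import stats

from .core_io import AnalyteParams, SampleTable
from .errors import ConfigError, MissingAnalyteError, ValidationError

__all__ = [
    "ConcentrationSummary",
    "ComplianceReport",
    "SpearmanResult",
    "summarize",
    "spearman_rho",
    "compliance_screen",
    "write_summary_table",
]


@dataclass(frozen=True)
class ConcentrationSummary:
    """Per-analyte summary: n, mean, SE, min, max, range (all µg/kg).

    ``sd`` (the n-1 sample standard deviation) is retained for the Monte
    Carlo module's variability mode, but the headline dispersion is the SE.
    """

    analyte: str
    n: int
    mean: float
    se: float
    min: float
    max: float
    range: float
    sd: float

    def __post_init__(self) -> None:
        # tolerate accumulation rounding: np.mean of n equal values can land
        # a few ulps outside [min, max]
        tol = 1e-12 * max(1.0, abs(self.mean))
        if not (self.min - tol <= self.mean <= self.max + tol):
            raise ValidationError("summary violates min <= mean <= max")


@dataclass(frozen=True)
class ComplianceReport:
    """Exceedance screen of one analyte against one regulatory maximum level."""

    analyte: str
    limit_name: str
    limit: float
    n_exceeding: int
    max_observed: float

    @property
    def compliant(self) -> bool:
        return self.n_exceeding == 0


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    pvalue: float
    n: int
    method: str


def _analysis_values(table: SampleTable, analyte: str) -> np.ndarray:
    """Concentrations for one analyte with censored records as LOQ/2."""
    vals = []
    for rec in table.for_analyte(analyte):
        if rec.censored:
            if rec.loq is None or not rec.loq > 0:
                raise ValidationError(
                    f"censored record {rec.sample_id!r}/{analyte!r} has no usable LOQ"
                )
            vals.append(rec.loq / 2.0)
        else:
            vals.append(rec.concentration)
    return np.asarray(vals, dtype=float)


def summarize(table: SampleTable, analyte: str) -> ConcentrationSummary:
    """Compute the concentration summary row for one analyte.

    Requires at least two records (the SE needs n >= 2). The range is
    max - min exactly; SE = SD/sqrt(n) with the n-1 denominator SD.
    """
    values = _analysis_values(table, analyte)
    n = values.size
    if n == 0:
        raise MissingAnalyteError(f"no records for analyte {analyte!r}")
    if n == 1:
        raise ValidationError(
            f"analyte {analyte!r} has a single record; the SE requires n >= 2"
        )
    sd = float(np.std(values, ddof=1))
    return ConcentrationSummary(
        analyte=analyte,
        n=int(n),
        mean=float(np.mean(values)),
        se=sd / float(np.sqrt(n)),
        min=float(np.min(values)),
        max=float(np.max(values)),
        range=float(np.max(values) - np.min(values)),
        sd=sd,
    )


def spearman_rho(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "t-approx",
    seed: int | None = None,
    n_perm: int = 10000,
) -> SpearmanResult:
    """Spearman rank correlation with a two-sided p-value.

    The coefficient is the Pearson correlation of mid-ranks (ties get
    average ranks). ``method="t-approx"`` uses the t approximation with
    n-2 degrees of freedom; ``method="permutation"`` estimates the p-value
    by seeded random permutation of ``y``, which is preferable at small n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValidationError("spearman_rho requires at least 3 paired observations")
    if np.ptp(stats.rankdata(x)) == 0 or np.ptp(stats.rankdata(y)) == 0:
        raise ValidationError("zero rank variance: correlation undefined")

    res = stats.spearmanr(x, y)
    rho = float(res.statistic)

    if method == "t-approx":
        pvalue = float(res.pvalue)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm_rho = stats.spearmanr(x, rng.permutation(y)).statistic
            if abs(perm_rho) >= abs(rho) - 1e-12:
                count += 1
        pvalue = (count + 1) / (n_perm + 1)
    else:
        raise ConfigError(f"unknown p-value method {method!r}")
    return SpearmanResult(rho=rho, pvalue=pvalue, n=int(x.size), method=method)


def compliance_screen(
    table: SampleTable, params: AnalyteParams, limit_name: str
) -> ComplianceReport:
    """Count records strictly above a regulatory maximum level.

    ``limit_name`` selects ``"faowho"`` or ``"isiri"``. The comparison is
    strict (a record exactly at the limit is not an exceedance), matching
    the compliance phrasing "lower than" the limit.
    """
    limits = {"faowho": params.ml_faowho, "isiri": params.ml_isiri}
    if limit_name not in limits:
        raise ConfigError(f"unknown limit selector {limit_name!r}; use 'faowho' or 'isiri'")
    limit = limits[limit_name]
    if limit is None:
        raise ConfigError(f"no {limit_name!r} limit configured for {params.name!r}")
    values = _analysis_values(table, params.name)
    if values.size == 0:
        raise MissingAnalyteError(f"no records for analyte {params.name!r}")
    return ComplianceReport(
        analyte=params.name,
        limit_name=limit_name,
        limit=float(limit),
        n_exceeding=int(np.sum(values > limit)),
        max_observed=float(np.max(values)),
    )


def write_summary_table(
    summaries: Iterable[ConcentrationSummary], dest: str | Path | IO[str]
) -> None:
    """Write summary rows as CSV: ``analyte,n,range,min,max,mean,se``."""
    rows = [
        [s.analyte, s.n, repr(s.range), repr(s.min), repr(s.max), repr(s.mean), repr(s.se)]
        for s in summaries
    ]
    header = ["analyte", "n", "range", "min", "max", "mean", "se"]
    if isinstance(dest, (str, Path)):
        with open(dest, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(header)
            w.writerows(rows)
    else:
        w = csv.writer(dest)
        w.writerow(header)
        w.writerows(rows)
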