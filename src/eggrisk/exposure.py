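"""Deterministic dietary exposure metrics.

The estimated daily intake of a contaminant through egg consumption is

    EDI = C * (FIR / 1000) / WAB        [µg/kg-bw/day]

with C the concentration in µg/kg wet weight, FIR the intake rate in
g/day (divided by 1000 to express the eaten mass in kg) and WAB the body
weight in kg. Weekly and monthly intakes are EWI = 7 * EDI and
EMI = 30 * EDI, compared against the JECFA provisional tolerable weekly
and monthly intakes (PTWI/PTMI). Two scenarios are assessed per analyte:
"overall" (the mean concentration) and "maximum" (the observed maximum).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

from .core_io import AnalyteParams, ExposureParams
from .errors import ConfigError, ValidationError
from .rounding import truncate_display
from .summary_stats import ConcentrationSummary

__all__ = [
    "WEEK_DAYS",
    "MONTH_DAYS",
    "Scenario",
    "ExposureResult",
    "compute_edi",
    "compute_ewi",
    "compute_emi",
    "tolerable_fraction",
    "exposure_table",
    "write_exposure_table",
]

WEEK_DAYS = 7.0
MONTH_DAYS = 30.0

SCENARIO_LABELS = ("overall", "maximum")


@dataclass(frozen=True)
class Scenario:
    """A named concentration choice: overall (mean) or maximum."""

    label: str
    concentration: float

    def __post_init__(self) -> None:
        if self.label not in SCENARIO_LABELS:
            raise ValidationError(f"scenario label must be one of {SCENARIO_LABELS}")
        if self.concentration < 0:
            raise ValidationError("scenario concentration must be >= 0")


@dataclass(frozen=True)
class ExposureResult:
    """EDI/EWI/EMI for one analyte under one scenario, with tolerable-intake fractions."""

    analyte: str
    scenario: Scenario
    edi: float
    ewi: float
    emi: float
    ptwi_fraction: float | None
    ptmi_fraction: float | None


def compute_edi(c: float, ep: ExposureParams) -> float:
    """Estimated daily intake in µg/kg-bw/day; linear and homogeneous in c."""
    return c * (ep.fir / 1000.0) / ep.wab


def compute_ewi(edi: float) -> float:
    """Estimated weekly intake: EDI x 7, µg/kg-bw/week."""
    return edi * WEEK_DAYS


def compute_emi(edi: float) -> float:
    """Estimated monthly intake: EDI x 30, µg/kg-bw/month."""
    return edi * MONTH_DAYS


def tolerable_fraction(intake: float, limit: float | None) -> float | None:
    """intake / provisional tolerable intake; ``None`` when no limit is set.

    Values below 1 mean the intake sits under the provisional tolerable
    level for the matching period (week for PTWI, month for PTMI).
    """
    if limit is None:
        return None
    if not limit > 0:
        raise ValidationError("tolerable intake limit must be > 0")
    return intake / limit


def exposure_table(
    summaries: Iterable[ConcentrationSummary],
    ep: ExposureParams,
    params: Mapping[str, AnalyteParams],
    scenarios: Sequence[str] = SCENARIO_LABELS,
) -> list[ExposureResult]:
    """One :class:`ExposureResult` per analyte per scenario, unrounded.

    The overall scenario uses the analyte's mean concentration and the
    maximum scenario its observed maximum. Display rounding is applied
    only by :func:`write_exposure_table`.
    """
    results: list[ExposureResult] = []
    for summary in summaries:
        if summary.analyte not in params:
            raise ConfigError(f"no analyte parameters configured for {summary.analyte!r}")
        ap = params[summary.analyte]
        for label in scenarios:
            c = summary.mean if label == "overall" else summary.max
            edi = compute_edi(c, ep)
            ewi = compute_ewi(edi)
            emi = compute_emi(edi)
            results.append(
                ExposureResult(
                    analyte=summary.analyte,
                    scenario=Scenario(label=label, concentration=c),
                    edi=edi,
                    ewi=ewi,
                    emi=emi,
                    ptwi_fraction=tolerable_fraction(ewi, ap.ptwi),
                    ptmi_fraction=tolerable_fraction(emi, ap.ptmi),
                )
            )
    return results


def display_intakes(result: ExposureResult) -> tuple[float, float, float]:
    """The published-table rendering of one exposure row.

    The EDI is truncated toward zero to one significant figure and the
    displayed EWI/EMI are 7x and 30x that truncated value, which is the
    only rule consistent with published triples such as 0.002/0.014/0.06.
    """
    edi_disp = truncate_display(result.edi, 1)
    return edi_disp, edi_disp * WEEK_DAYS, edi_disp * MONTH_DAYS


def write_exposure_table(
    results: Iterable[ExposureResult],
    dest: str | Path | IO[str],
    paper_rounding: bool = False,
) -> None:
    """Write exposure rows as CSV.

    Columns: ``analyte,scenario,edi,ewi,emi,ptwi_fraction,ptmi_fraction``.
    With ``paper_rounding`` the EDI/EWI/EMI cells use the published-table
    display convention (see :func:`display_intakes`); otherwise full
    precision is written.
    """
    header = ["analyte", "scenario", "edi", "ewi", "emi", "ptwi_fraction", "ptmi_fraction"]
    rows = []
    for r in results:
        if paper_rounding:
            # tidy the binary-float dust left by 7x/30x of a truncated value
            cells = [format(v, ".6g") for v in display_intakes(r)]
        else:
            cells = [repr(v) for v in (r.edi, r.ewi, r.emi)]
        rows.append(
            [
                r.analyte,
                r.scenario.label,
                *cells,
                "" if r.ptwi_fraction is None else repr(r.ptwi_fraction),
                "" if r.ptmi_fraction is None else repr(r.ptmi_fraction),
            ]
        )
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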