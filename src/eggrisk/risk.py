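"""Non-carcinogenic (THQ) and carcinogenic (ILCR) risk metrics.

The target hazard quotient compares chronic daily exposure with the oral
reference dose RfD (mg/kg-bw/day):

    THQ = (EF * ED / TA) * EDI_mg / RfD

where EDI_mg is the estimated daily intake in mg/kg-bw/day. With the
standard non-carcinogen averaging time TA = EF * ED the prefactor is 1 and
THQ reduces exactly to EDI_mg / RfD. THQ < 1 is read as no appreciable
non-carcinogenic risk.

The incremental lifetime cancer risk multiplies the lifetime average daily
dose by the cancer slope factor CSF (per mg/kg-bw/day):

    ILCR = EDI * CSF

Two unit conventions are provided and the choice is mandatory. ``strict``
feeds the CSF the dimensionally matching EDI in mg/kg-bw/day. ``paper``
feeds it the EDI in µg/kg-bw/day, which is 1000x larger; published egg
assessments that report Pb ILCR values of order 1e-5 from µg/kg
concentrations follow this convention, so it is needed for comparability
with that literature. ILCR bands follow the US-EPA screening thresholds:
< 1e-6 negligible, 1e-6..1e-4 acceptable, 1e-4..1e-3 high, >= 1e-3 very
high (boundaries belong to the higher band).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

from .core_io import AnalyteParams, ExposureParams
from .errors import ConfigError, ValidationError
from .exposure import SCENARIO_LABELS, Scenario, compute_edi
from .rounding import round_display, truncate_display  # noqa: F401  (re-export)
from .summary_stats import ConcentrationSummary

__all__ = [
    "ILCR_MODES",
    "RISK_BANDS",
    "RiskResult",
    "compute_thq",
    "compute_ilcr",
    "classify_ilcr",
    "hazard_index",
    "risk_table",
    "write_risk_table",
    "round_display",
    "truncate_display",
]

ILCR_MODES = ("paper", "strict")

#: Band label -> (lower bound inclusive, upper bound exclusive) on ILCR.
RISK_BANDS: Mapping[str, tuple[float, float]] = {
    "negligible": (0.0, 1e-6),
    "acceptable": (1e-6, 1e-4),
    "high": (1e-4, 1e-3),
    "very_high": (1e-3, float("inf")),
}


@dataclass(frozen=True)
class RiskResult:
    """THQ and (when a CSF exists) ILCR for one analyte under one scenario."""

    analyte: str
    scenario: Scenario
    thq: float
    ilcr: float | None
    band: str | None
    ilcr_mode: str


def compute_thq(c, ep: ExposureParams, ap: AnalyteParams):
    """Target hazard quotient for concentration ``c`` (µg/kg, scalar or array)."""
    if not ap.rfd > 0:
        raise ConfigError(f"rfd must be > 0 for {ap.name!r}")
    edi_mg = compute_edi(c, ep) / 1000.0
    return (ep.ef * ep.ed / ep.ta) * edi_mg / ap.rfd


def compute_ilcr(c, ep: ExposureParams, ap: AnalyteParams, mode: str):
    """Incremental lifetime cancer risk; ``None`` when the analyte has no CSF.

    ``mode`` must be ``"paper"`` (EDI in µg/kg-bw/day) or ``"strict"``
    (EDI in mg/kg-bw/day, 1000x smaller); see the module docstring.
    """
    if mode not in ILCR_MODES:
        raise ConfigError(f"ilcr mode must be one of {ILCR_MODES}, got {mode!r}")
    if ap.csf is None:
        return None
    edi = compute_edi(c, ep)
    if mode == "strict":
        edi = edi / 1000.0
    return edi * ap.csf


def classify_ilcr(ilcr: float) -> str:
    """US-EPA screening band for an ILCR value (lower boundary inclusive)."""
    if ilcr < 0:
        raise ValidationError("ILCR must be >= 0")
    for label, (lo, hi) in RISK_BANDS.items():
        if lo <= ilcr < hi:
            return label
    raise ValidationError(f"unclassifiable ILCR {ilcr!r}")  # pragma: no cover


def hazard_index(results: Iterable[RiskResult], scenario: str = "overall") -> float:
    """Sum of THQs across analytes for one scenario (optional reporting extra).

    Off by default in all report paths: single-food egg assessments
    conventionally report per-metal THQs without summation.
    """
    return sum(r.thq for r in results if r.scenario.label == scenario)


def risk_table(
    summaries: Iterable[ConcentrationSummary],
    ep: ExposureParams,
    params: Mapping[str, AnalyteParams],
    ilcr_mode: str,
    scenarios: Sequence[str] = SCENARIO_LABELS,
) -> list[RiskResult]:
    """One :class:`RiskResult` per analyte per scenario, unrounded."""
    results: list[RiskResult] = []
    for summary in summaries:
        if summary.analyte not in params:
            raise ConfigError(f"no analyte parameters configured for {summary.analyte!r}")
        ap = params[summary.analyte]
        for label in scenarios:
            c = summary.mean if label == "overall" else summary.max
            thq = float(compute_thq(c, ep, ap))
            ilcr = compute_ilcr(c, ep, ap, mode=ilcr_mode)
            results.append(
                RiskResult(
                    analyte=summary.analyte,
                    scenario=Scenario(label=label, concentration=c),
                    thq=thq,
                    ilcr=None if ilcr is None else float(ilcr),
                    band=None if ilcr is None else classify_ilcr(float(ilcr)),
                    ilcr_mode=ilcr_mode,
                )
            )
    return results


def write_risk_table(results: Iterable[RiskResult], dest: str | Path | IO[str]) -> None:
    """Write risk rows as CSV: ``analyte,scenario,thq,ilcr,band,mode``."""
    header = ["analyte", "scenario", "thq", "ilcr", "band", "mode"]
    rows = [
        [
            r.analyte,
            r.scenario.label,
            repr(r.thq),
            "" if r.ilcr is None else repr(r.ilcr),
            "" if r.band is None else r.band,
            r.ilcr_mode,
        ]
        for r in results
    ]
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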