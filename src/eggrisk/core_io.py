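"""Data model and I/O for egg contaminant concentration data.

Concentrations are carried internally in micrograms per kilogram (µg/kg)
wet weight everywhere; unit conversion happens only at the I/O boundary.
Left-censored measurements (below the limit of quantification, LOQ) are
flagged per record and substituted as LOQ/2 for analysis.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

import pandas as pd
import yaml

from .errors import ConfigError, FormatError, ValidationError

__all__ = [
    "SampleRecord",
    "SampleTable",
    "AnalyteParams",
    "ExposureParams",
    "read_samples",
    "write_samples",
    "substitute_loq",
    "load_config",
    "default_analyte_params",
    "default_exposure_params",
    "CENSOR_SENTINEL",
    "UNIT_FACTORS",
]

#: Accepted spellings of the supported concentration units, mapped to the
#: multiplicative factor that converts them to µg/kg.
UNIT_FACTORS: Mapping[str, float] = {
    "ug/kg": 1.0,
    "µg/kg": 1.0,
    "μg/kg": 1.0,
    "ppb": 1.0,
    "mg/kg": 1000.0,
}

#: Literal accepted in the concentration column to mark a censored value.
CENSOR_SENTINEL = "<LOQ"

_REQUIRED_COLUMNS = ("sample_id", "brand", "analyte", "concentration")
_ALL_COLUMNS = ("sample_id", "brand", "analyte", "concentration", "censored", "loq")


@dataclass(frozen=True)
class SampleRecord:
    """One measured concentration of one analyte in one egg.

    Parameters
    ----------
    sample_id : str
        Free-text egg identifier; unique per analyte within a table.
    brand : str
        Brand / batch label (the study design samples eggs in brand pairs).
    analyte : str
        Analyte label, e.g. ``"Pb"`` or ``"Cd"``.
    concentration : float
        Concentration in µg/kg wet weight. For a censored record this is
        0.0 until :func:`substitute_loq` replaces it by ``loq / 2``.
    censored : bool
        True when the measurement fell below the limit of quantification.
    loq : float, optional
        Limit of quantification in µg/kg; required when ``censored``.
    """

    sample_id: str
    brand: str
    analyte: str
    concentration: float
    censored: bool = False
    loq: float | None = None

    def __post_init__(self) -> None:
        if not self.analyte:
            raise ValidationError("analyte label must be non-empty")
        if not (self.concentration >= 0):
            raise ValidationError(
                f"concentration must be >= 0, got {self.concentration!r} "
                f"(sample {self.sample_id!r}, analyte {self.analyte!r})"
            )
        if self.censored and (self.loq is None or not self.loq > 0):
            raise ValidationError(
                f"censored record {self.sample_id!r}/{self.analyte!r} requires loq > 0"
            )


@dataclass(frozen=True)
class SampleTable:
    """An ordered collection of :class:`SampleRecord` with provenance metadata."""

    records: tuple[SampleRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            key = (rec.sample_id, rec.analyte)
            if key in seen:
                raise ValidationError(f"duplicate (sample_id, analyte) pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SampleRecord]:
        return iter(self.records)

    def analytes(self) -> tuple[str, ...]:
        """Distinct analyte labels in first-appearance order."""
        out: list[str] = []
        for rec in self.records:
            if rec.analyte not in out:
                out.append(rec.analyte)
        return tuple(out)

    def for_analyte(self, analyte: str) -> tuple[SampleRecord, ...]:
        return tuple(r for r in self.records if r.analyte == analyte)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.records],
                "brand": [r.brand for r in self.records],
                "analyte": [r.analyte for r in self.records],
                "concentration": [r.concentration for r in self.records],
                "censored": [r.censored for r in self.records],
                "loq": [r.loq for r in self.records],
            }
        )


@dataclass(frozen=True)
class AnalyteParams:
    """Toxicological and regulatory parameters for one analyte.

    ``rfd`` is the oral reference dose in mg/kg-bw/day; ``csf`` the cancer
    slope factor per mg/kg-bw/day (absent when no oral slope has been
    established, e.g. Cd); ``ptwi``/``ptmi`` the JECFA provisional tolerable
    weekly/monthly intakes in µg/kg-bw per week/month; ``ml_faowho`` and
    ``ml_isiri`` regulatory maximum levels in µg/kg.
    """

    name: str
    rfd: float
    csf: float | None = None
    ptwi: float | None = None
    ptmi: float | None = None
    ml_faowho: float | None = None
    ml_isiri: float | None = None

    def __post_init__(self) -> None:
        if not self.rfd > 0:
            raise ValidationError(f"rfd must be > 0 for {self.name!r}")
        if self.csf is not None and self.csf < 0:
            raise ValidationError(f"csf must be >= 0 for {self.name!r}")
        for attr in ("ptwi", "ptmi", "ml_faowho", "ml_isiri"):
            v = getattr(self, attr)
            if v is not None and not v > 0:
                raise ValidationError(f"{attr} must be > 0 when present ({self.name!r})")


@dataclass(frozen=True)
class ExposureParams:
    """Adult chronic-exposure scenario parameters.

    fir : egg intake rate, g/day; wab : body weight, kg;
    ef : exposure frequency, days/year; ed : exposure duration, years;
    ta : averaging time, days (equal to ef x ed for non-carcinogens).
    """

    fir: float = 25.4
    wab: float = 70.0
    ef: float = 365.0
    ed: float = 70.0
    ta: float = 25550.0

    def __post_init__(self) -> None:
        for attr in ("fir", "wab", "ef", "ed", "ta"):
            if not getattr(self, attr) > 0:
                raise ValidationError(f"{attr} must be > 0")


def default_exposure_params() -> ExposureParams:
    """The adult scenario: 25.4 g eggs/day, 70 kg body weight, lifetime averaging."""
    return ExposureParams()


def default_analyte_params() -> dict[str, AnalyteParams]:
    """Pb and Cd parameter bundles (RfD, CSF, PTWI/PTMI, maximum levels)."""
    return {
        "Pb": AnalyteParams(
            name="Pb", rfd=0.004, csf=0.0085, ptwi=25.0,
            ml_faowho=500.0, ml_isiri=100.0,
        ),
        "Cd": AnalyteParams(
            name="Cd", rfd=0.001, csf=None, ptwi=7.0, ptmi=25.0,
            ml_faowho=50.0, ml_isiri=50.0,
        ),
    }


def _as_text_stream(source: str | Path | IO[str]) -> IO[str]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8")
    return source


def read_samples(source: str | Path | IO[str], unit: str = "µg/kg") -> SampleTable:
    """Read a per-sample concentration CSV into a :class:`SampleTable`.

    The CSV must have a header with at least
    ``sample_id, brand, analyte, concentration``; optional ``censored`` and
    ``loq`` columns carry the censoring metadata. A censored value may be
    written as an empty concentration cell, the literal ``"<LOQ"``, or an
    explicit true in the ``censored`` column. Concentrations are converted
    from ``unit`` (µg/kg, mg/kg or ppb) to µg/kg on read; row order is kept.
    """
    if unit not in UNIT_FACTORS:
        raise ConfigError(
            f"unsupported unit {unit!r}; expected one of {sorted(set(UNIT_FACTORS))}"
        )
    factor = UNIT_FACTORS[unit]

    stream = _as_text_stream(source)
    df = pd.read_csv(stream, dtype=str, keep_default_na=False)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")

    records: list[SampleRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        raw_conc = getattr(row, "concentration").strip()
        raw_cens = getattr(row, "censored", "").strip().lower() if "censored" in df.columns else ""
        raw_loq = getattr(row, "loq", "").strip() if "loq" in df.columns else ""

        censored = raw_conc in ("", CENSOR_SENTINEL) or raw_cens in ("true", "1", "yes")
        loq = float(raw_loq) * factor if raw_loq else None
        if raw_conc in ("", CENSOR_SENTINEL):
            conc = 0.0
        else:
            conc = float(raw_conc)
            if conc < 0:
                raise ValidationError(f"negative concentration {conc} at row {i}")
            conc *= factor
        try:
            records.append(
                SampleRecord(
                    sample_id=getattr(row, "sample_id"),
                    brand=getattr(row, "brand"),
                    analyte=getattr(row, "analyte"),
                    concentration=conc,
                    censored=censored,
                    loq=loq,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc

    name = getattr(stream, "name", "<stream>")
    return SampleTable(records=tuple(records), provenance=f"read from {name} ({unit})")


def write_samples(table: SampleTable, dest: str | Path | IO[str]) -> None:
    """Write a table to the standard samples CSV (always in µg/kg).

    Censored records keep their stored concentration (0.0 before
    substitution, LOQ/2 after) so that write -> read round-trips exactly.
    """
    df = table.to_dataframe()
    df["censored"] = df["censored"].map(lambda b: "true" if b else "false")
    df["loq"] = df["loq"].map(lambda v: "" if v is None or pd.isna(v) else repr(float(v)))
    df["concentration"] = df["concentration"].map(lambda v: repr(float(v)))
    if isinstance(dest, (str, Path)):
        df.to_csv(dest, index=False)
    else:
        df.to_csv(dest, index=False)


def substitute_loq(table: SampleTable) -> SampleTable:
    """Replace each censored concentration by LOQ/2 (non-mutating, idempotent).

    Uncensored records pass through unchanged; censored records keep their
    flag so downstream summaries can report the censoring fraction.
    """
    out: list[SampleRecord] = []
    for rec in table.records:
        if rec.censored:
            if rec.loq is None or not rec.loq > 0:
                raise ValidationError(
                    f"censored record {rec.sample_id!r}/{rec.analyte!r} has no usable LOQ"
                )
            out.append(replace(rec, concentration=rec.loq / 2.0))
        else:
            out.append(rec)
    return SampleTable(records=tuple(out), provenance=table.provenance + " | LOQ/2 substituted")


_EXPOSURE_KEYS = {
    "fir_g_per_day": "fir",
    "wab_kg": "wab",
    "ef_days_per_year": "ef",
    "ed_years": "ed",
    "ta_days": "ta",
}
_ANALYTE_KEYS = ("rfd", "csf", "ptwi", "ptmi", "ml_faowho", "ml_isiri")


def load_config(
    source: str | Path | IO[str] | Mapping | None = None,
) -> tuple[ExposureParams, dict[str, AnalyteParams]]:
    """Load exposure and analyte parameters from a YAML config.

    An empty or absent config yields the default adult Pb/Cd assessment
    bundle. Recognised keys are ``exposure.{fir_g_per_day, wab_kg,
    ef_days_per_year, ed_years, ta_days}`` and
    ``analyte.<name>.{rfd, csf, ptwi, ptmi, ml_faowho, ml_isiri}``; unknown
    keys produce a warning, not an error. An exposure bundle whose
    ef x ed differs from ta is accepted with a warning.
    """
    if source is None:
        data: Mapping = {}
    elif isinstance(source, Mapping):
        data = source
    else:
        stream = _as_text_stream(source)
        data = yaml.safe_load(stream.read()) or {}

    for key in data:
        if key not in ("exposure", "analyte"):
            warnings.warn(f"unknown config section {key!r} ignored", stacklevel=2)

    exposure_kwargs: dict[str, float] = {}
    for key, value in (data.get("exposure") or {}).items():
        if key not in _EXPOSURE_KEYS:
            warnings.warn(f"unknown exposure key {key!r} ignored", stacklevel=2)
            continue
        exposure_kwargs[_EXPOSURE_KEYS[key]] = float(value)
    ep = ExposureParams(**exposure_kwargs)
    if not math.isclose(ep.ef * ep.ed, ep.ta, rel_tol=1e-9):
        warnings.warn(
            f"averaging time ta={ep.ta} differs from ef*ed={ep.ef * ep.ed}; "
            "THQ no longer reduces to EDI/RfD",
            stacklevel=2,
        )

    analytes = default_analyte_params()
    for name, block in (data.get("analyte") or {}).items():
        base = analytes.get(name)
        kwargs = {
            "name": name,
            "rfd": base.rfd if base else None,
            "csf": base.csf if base else None,
            "ptwi": base.ptwi if base else None,
            "ptmi": base.ptmi if base else None,
            "ml_faowho": base.ml_faowho if base else None,
            "ml_isiri": base.ml_isiri if base else None,
        }
        for key, value in (block or {}).items():
            if key not in _ANALYTE_KEYS:
                warnings.warn(f"unknown analyte key {name}.{key!r} ignored", stacklevel=2)
                continue
            kwargs[key] = None if value is None else float(value)
        if kwargs["rfd"] is None:
            raise ConfigError(f"analyte {name!r} config must supply rfd")
        analytes[name] = AnalyteParams(**kwargs)

    return ep, analytes
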