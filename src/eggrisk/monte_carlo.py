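"""Seeded Monte Carlo propagation of input uncertainty through THQ/ILCR.

The concentration entering the risk equations is uncertain; this module
draws it (and optionally the intake rate and body weight) from configured
distributions, maps every draw through the deterministic risk operations,
and summarises the resulting THQ and ILCR distributions by their empirical
percentiles (5th, 50th, 95th by default — the 95th is the conventional
criterion for the exposed-population upper bound).

The default uncertainty model samples the concentration from a normal
distribution centred on the sample mean with the standard error as scale
(uncertainty of the mean), truncated at zero; intake rate and body weight
are point values. A variability mode instead uses the sample SD
(SD = SE * sqrt(n)), describing person-to-person spread rather than
uncertainty of the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_io import AnalyteParams, ExposureParams
from .errors import ConfigError, SamplingError
from .risk import classify_ilcr, compute_ilcr, compute_thq
from .summary_stats import ConcentrationSummary

__all__ = [
    "DistributionSpec",
    "MCConfig",
    "MCResult",
    "sample",
    "run_mc",
    "percentile",
    "cumulative_curve",
    "default_mc_config",
]

_FAMILIES = ("point", "normal", "lognormal", "uniform", "triangular")

#: Retry rounds for rejection sampling before declaring the truncation infeasible.
_MAX_REJECTION_ROUNDS = 1000


@dataclass(frozen=True)
class DistributionSpec:
    """One input distribution: family, parameters and a lower truncation bound.

    Families and parameters:

    - ``point``: ``value``
    - ``normal``: ``mean``, ``sd``
    - ``lognormal``: ``mean_log``, ``sd_log`` (of the underlying normal)
    - ``uniform``: ``low``, ``high``
    - ``triangular``: ``low``, ``mode``, ``high``

    Draws below ``truncate_low`` (default 0, concentrations and body
    weights being non-negative) are rejected and resampled.
    """

    family: str
    params: Mapping[str, float]
    truncate_low: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigError(f"unknown distribution family {self.family!r}")
        object.__setattr__(self, "params", dict(self.params))
        scale_keys = {"normal": "sd", "lognormal": "sd_log"}
        if self.family in scale_keys:
            if not self.params.get(scale_keys[self.family], 0.0) > 0:
                raise ConfigError(f"{self.family} scale parameter must be > 0")


@dataclass(frozen=True)
class MCConfig:
    """Simulation settings: iteration count, seed, percentiles, input specs."""

    seed: int
    n_iter: int = 1000
    percentiles: tuple[float, ...] = (5.0, 50.0, 95.0)
    specs: Mapping[str, DistributionSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ConfigError("n_iter must be >= 1")
        if any(not (0 < p < 100) for p in self.percentiles):
            raise ConfigError("percentile probabilities must lie in (0, 100)")
        object.__setattr__(self, "percentiles", tuple(self.percentiles))
        object.__setattr__(self, "specs", dict(self.specs))


@dataclass(frozen=True)
class MCResult:
    """Draws and percentile summary for one output variable (thq or ilcr)."""

    variable: str
    analyte: str
    draws: np.ndarray
    mean: float
    percentile_values: dict[float, float]
    seed: int
    config: MCConfig

    @property
    def band(self) -> str | None:
        """US-EPA band of the 95th-percentile ILCR (None for THQ variables)."""
        if self.variable != "ilcr" or 95.0 not in self.percentile_values:
            return None
        return classify_ilcr(self.percentile_values[95.0])


def _draw_once(spec: DistributionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    p = spec.params
    if spec.family == "point":
        return np.full(n, float(p["value"]))
    if spec.family == "normal":
        return rng.normal(p["mean"], p["sd"], size=n)
    if spec.family == "lognormal":
        return rng.lognormal(p["mean_log"], p["sd_log"], size=n)
    if spec.family == "uniform":
        return rng.uniform(p["low"], p["high"], size=n)
    if spec.family == "triangular":
        return rng.triangular(p["low"], p["mode"], p["high"], size=n)
    raise ConfigError(f"unknown family {spec.family!r}")  # pragma: no cover


def sample(spec: DistributionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` values from ``spec``, rejection-resampling below the bound."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    values = _draw_once(spec, n, rng)
    if spec.family == "point":
        if values.size and values[0] < spec.truncate_low:
            raise SamplingError("point value lies below the truncation bound")
        return values
    rounds = 0
    bad = values < spec.truncate_low
    while bad.any():
        rounds += 1
        if rounds > _MAX_REJECTION_ROUNDS:
            raise SamplingError(
                f"truncation at {spec.truncate_low} looks infeasible for {spec.family}"
            )
        values[bad] = _draw_once(spec, int(bad.sum()), rng)
        bad = values < spec.truncate_low
    return values


def percentile(draws: Sequence[float], p: float) -> float:
    """Empirical quantile with linear interpolation between order statistics."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ConfigError("draws must be non-empty")
    if not (0 < p < 100):
        raise ConfigError("p must lie in (0, 100)")
    return float(np.percentile(draws, p, method="linear"))


def cumulative_curve(draws: Sequence[float]) -> np.ndarray:
    """Empirical CDF points (value, cumulative probability), both nondecreasing."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ConfigError("draws must be non-empty")
    xs = np.sort(draws)
    ps = np.arange(1, xs.size + 1) / xs.size
    return np.column_stack([xs, ps])


def default_mc_config(
    summary: ConcentrationSummary,
    ep: ExposureParams,
    seed: int,
    n_iter: int = 1000,
    uncertainty: str = "se",
) -> MCConfig:
    """The default uncertainty model for one analyte.

    Concentration ~ normal(mean, SE) truncated at 0 — or normal(mean, SD)
    with ``uncertainty="sd"`` for the variability mode — with point-valued
    intake rate and body weight.
    """
    if uncertainty not in ("se", "sd"):
        raise ConfigError("uncertainty must be 'se' or 'sd'")
    scale = summary.se if uncertainty == "se" else summary.sd
    return MCConfig(
        seed=seed,
        n_iter=n_iter,
        specs={
            "concentration": DistributionSpec(
                "normal", {"mean": summary.mean, "sd": scale}, truncate_low=0.0
            ),
            "fir": DistributionSpec("point", {"value": ep.fir}),
            "wab": DistributionSpec("point", {"value": ep.wab}),
        },
    )


def run_mc(
    summary: ConcentrationSummary,
    ep: ExposureParams,
    ap: AnalyteParams,
    cfg: MCConfig,
    ilcr_mode: str = "paper",
) -> list[MCResult]:
    """Propagate the configured input distributions through THQ (and ILCR).

    Returns one :class:`MCResult` for THQ and, when the analyte has a
    cancer slope factor, one for ILCR. Identical configs (seed included)
    reproduce the draw vectors bit for bit.
    """
    if "concentration" not in cfg.specs:
        raise ConfigError("MCConfig.specs must include a 'concentration' spec")
    rng = np.random.default_rng(cfg.seed)
    conc = sample(cfg.specs["concentration"], cfg.n_iter, rng)

    fir_spec = cfg.specs.get("fir", DistributionSpec("point", {"value": ep.fir}))
    wab_spec = cfg.specs.get("wab", DistributionSpec("point", {"value": ep.wab}))

    if fir_spec.family == "point" and wab_spec.family == "point":
        ep_draw = replace(ep, fir=float(fir_spec.params["value"]),
                          wab=float(wab_spec.params["value"]))
        thq = np.asarray(compute_thq(conc, ep_draw, ap), dtype=float)
        ilcr = compute_ilcr(conc, ep_draw, ap, mode=ilcr_mode)
    else:
        fir = sample(fir_spec, cfg.n_iter, rng)
        wab = sample(wab_spec, cfg.n_iter, rng)
        thq = np.empty(cfg.n_iter)
        ilcr = np.empty(cfg.n_iter) if ap.csf is not None else None
        for i in range(cfg.n_iter):
            ep_i = replace(ep, fir=float(fir[i]), wab=float(wab[i]))
            thq[i] = compute_thq(conc[i], ep_i, ap)
            if ilcr is not None:
                ilcr[i] = compute_ilcr(conc[i], ep_i, ap, mode=ilcr_mode)

    def _result(variable: str, draws: np.ndarray) -> MCResult:
        return MCResult(
            variable=variable,
            analyte=summary.analyte,
            draws=draws,
            mean=float(np.mean(draws)),
            percentile_values={p: percentile(draws, p) for p in cfg.percentiles},
            seed=cfg.seed,
            config=cfg,
        )

    results = [_result("thq", thq)]
    if ilcr is not None:
        results.append(_result("ilcr", np.asarray(ilcr, dtype=float)))
    return results


def plot_cdf(result: MCResult, dest) -> None:
    """Save the empirical cumulative-probability curve of one MC result."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    curve = cumulative_curve(result.draws)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve[:, 0], curve[:, 1], drawstyle="steps-post")
    p95 = result.percentile_values.get(95.0)
    if p95 is not None:
        ax.axvline(p95, color="crimson", linestyle="--", linewidth=1,
                   label=f"95th pct = {p95:.3g}")
        ax.legend(frameon=False)
    ax.set_xlabel(f"{result.variable.upper()} ({result.analyte})")
    ax.set_ylabel("cumulative probability")
    fig.tight_layout()
    fig.savefig(dest)
    plt.close(fig)
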