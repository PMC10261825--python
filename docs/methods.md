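# Methods

## Scope and data model

The package assesses chronic adult dietary exposure to Pb and Cd through hen
egg consumption from a per-sample concentration table. Concentrations are
held in µg/kg wet weight throughout; the only unit conversions happen at the
I/O boundary (mg/kg and ppb are accepted on read, ×1000 and ×1
respectively). A sample record carries an egg identifier, a brand label, an
analyte label, the concentration, a censoring flag and the limit of
quantification (LOQ). The (sample, analyte) pair is unique within a table
and tables are immutable; every transformation returns a new table.

## Censoring

Measurements below the LOQ are left-censored. The substitution rule is the
conventional LOQ/2: `substitute_loq` replaces the withheld concentration by
half the record's LOQ while keeping the censoring flag, so downstream
reports can still state the censoring fraction. The operation is idempotent
and non-mutating. Summary statistics and compliance screens always use the
substituted value, whether or not the caller ran the substitution
explicitly. LOQ/2 is a simple imputation: it biases the mean upward when
the true below-LOQ distribution is concentrated near zero, and no
distributional (e.g. maximum-likelihood censored-normal) alternative is
offered because the assessment convention being implemented uses LOQ/2.

## Summary statistics

Per analyte: n, mean, standard error (SD/√n with the n−1 SD), min, max and
range = max − min. The SE is the headline dispersion because market-basket
surveys report mean ± SE; the SD is retained on the summary object for the
Monte Carlo variability mode. The Pb–Cd association is Spearman's rank
correlation (Pearson correlation of mid-ranks; ties get average ranks),
with a two-sided p-value from the t approximation on n−2 degrees of
freedom, or from a seeded permutation test (`method="permutation"`)
preferable at small n. Compliance screening counts records strictly above a
maximum level — a value exactly at the limit is compliant, matching the
"lower than the limit" convention — against FAO/WHO (Pb 500, Cd 50 µg/kg)
or ISIRI/Codex (Pb 100, Cd 50 µg/kg) limits.

## Exposure and risk

EDI = C·(FIR/1000)/WAB in µg/kg-bw/day; EWI = 7·EDI; EMI = 30·EDI, with
week = 7 days and month = 30 days as fixed constants (the only choice
consistent with published triples like 0.002 / 0.014 / 0.06). Intakes are
compared with PTWI (Pb 25, Cd 7 µg/kg-bw/week) and PTMI (Cd 25
µg/kg-bw/month; a PTMI is configured only for Cd because JECFA moved Cd to
a monthly basis given its long biological half-life). Two scenarios are
computed per analyte: "overall" at the mean and "maximum" at the observed
maximum concentration.

THQ = (EF·ED/TA)·EDI_mg/RfD. With the default bundle (EF 365 d/y, ED 70 y,
TA 25550 d = EF·ED) this reduces exactly to EDI_mg/RfD, and the identity
THQ·RfD = EDI/1000 holds to machine precision — it is enforced as a
property test.

ILCR = EDI·CSF with a mandatory unit mode. `strict` feeds the CSF
(defined per mg/kg-bw/day) the EDI in mg/kg-bw/day. `paper` feeds it the
EDI in µg/kg-bw/day, which is 1000× larger; the published egg-survey
literature that reports Pb ILCR ≈ 2e-5 from µg/kg concentrations follows
this convention, so it is provided — explicitly and logged — for
comparability, without silently endorsing the unit mismatch. Band
boundaries (1e-6, 1e-4, 1e-3) are closed on the lower end: a value exactly
at a boundary falls in the higher band. Cd has no established oral cancer
slope factor, so its ILCR is absent (None), never zero. A hazard-index sum
of THQs across analytes exists but is off by default in every report path;
single-food assessments conventionally do not sum.

## Display rounding

Published tables use two different conventions, both implemented in
`rounding.py`. Risk values round half-away-from-zero to significant figures
(0.000649 → 0.0006 at one figure). Exposure tables truncate the EDI toward
zero to one significant figure and then form the displayed EWI/EMI as 7×
and 30× the *truncated* EDI (0.0025973 → 0.002 → 0.014 / 0.06); this is the
only rule that reproduces all three cells of the published Pb row
simultaneously. All internal values are carried unrounded; rounding is
applied only by the report layer, behind the `--paper-rounding` flag.

## Monte Carlo

The default uncertainty model samples the concentration from
normal(mean, SE) truncated at zero — SE because the summary reports
mean ± SE, i.e. uncertainty about the mean — with point-valued intake rate
and body weight. A variability mode (`uncertainty="sd"`, SD = SE·√n)
describes person-to-person spread instead. Further families (lognormal,
uniform, triangular) are available per input. Truncation is enforced by
rejection resampling with a bounded retry budget (1000 rounds; an
infeasible bound raises). Draws are generated by a `numpy` Generator seeded
from the mandatory seed, so identical configurations are bit-identical
across runs. Each draw is mapped through the risk module's own THQ/ILCR
operations; percentiles (5/50/95 by default) use linear interpolation
between order statistics — the estimator of the commercial tool being
replaced is undocumented, and the linear-interpolation choice is testable
against the closed-form normal quantile: since THQ is linear in the
concentration, the 95th-percentile THQ converges to THQ(µ + 1.6449σ), and
at 10⁵ iterations the relative error is under 1% (tested). 1000 iterations
is the default, matching the convention of the assessments this mirrors.

Two published Monte Carlo figures from the same family of assessments (a
Cd THQ p95 of 0.002 and a Pb ILCR p95 of 2.5e-5) are not reproducible
under any single SE-vs-SD convention that also reproduces the Pb THQ p95
of 0.0007; the input distributions behind them were never disclosed. The
package therefore treats only the Pb THQ p95 as a reproduction target and
exposes both conventions as explicit flags.

## Synthetic data

No raw per-egg dataset is deposited for this kind of survey, so the
generator emulates its statistical structure: 21 brands × 2 eggs = 42
samples; Pb and Cd marginals targeting mean 7.158 (SD 1.607) and 2.83
(SD 0.979) µg/kg — SDs back-calculated as SE·√42 from the published SEs;
values clamped (not rejected) to the published envelopes 2.400–9.000 and
1.190–5.000 µg/kg; a Pb–Cd Spearman correlation of 0.35 induced by a
Gaussian copula whose latent Pearson correlation is 2·sin(π·ρₛ/6); and
optional left-censoring below a per-analyte LOQ, emitted as censored
records with the concentration withheld.

Because the Pb upper bound sits only ~1.1 SD above the target mean,
clamping would bias the sample mean low by ~0.10 µg/kg. The generator
therefore calibrates the pre-clamp location analytically: the clipped
normal's mean has a closed form, and the location solving
E[clip(X)] = target is found by root bracketing. The achieved moments,
correlation and censoring fraction are computed from the emitted table by
the summary module itself and disclosed in a generator report. Exact
moment or correlation recovery at n = 42 is not promised: across 100 fixed
seeds the sample means stay within 3 SE of target (tested), and at n = 5000
the empirical Spearman is within ±0.05 of 0.35 (tested).

What the generator does not emulate: within-brand correlation (eggs are
exchangeable within brands; the batch structure of real farms is unknown),
feed/water contamination transfer, measurement error and analytical drift,
and any non-normal skew in the true concentration distribution. Passing
tests on synthetic data therefore validate the pipeline's arithmetic,
conventions and statistical contracts — not claims about real Iranian eggs.

## Numerical and design choices

- Strict ">" for exceedance, lower-closed risk bands, mid-ranks for ties:
  each matches the stated convention of the assessment being mirrored, and
  each boundary case is pinned by a unit test.
- CSV round-trips write floats with `repr` so read(write(x)) is exact.
- `ExposureParams` with EF·ED ≠ TA is accepted with a warning (the THQ
  prefactor then no longer cancels); the default bundle satisfies equality.
- Problem sizes in the test suite (10⁵ Monte Carlo draws for convergence
  checks, 100 generator seeds, n = 5000 copula checks) were chosen as the
  smallest sizes at which the CLT/convergence tolerances being asserted are
  comfortably stable.

## Known limitations

Adults only (no age stratification); ingestion route only (no dermal or
inhalation terms); single-food exposure (no whole-diet aggregation); LOQ/2
is the only censoring treatment; no distribution auto-fitting to raw data
and no rank-correlation induction between Monte Carlo inputs.
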