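# Methods

## The model

The package quantifies cancer risk for an urban population breathing
asbestos fibers, starting from one city-wide annual mean airborne
concentration `C` (PCM fibers per milliliter) per calendar year. Three
exposure metrics are derived, all linear in `C`:

| quantity | definition | units | role |
|---|---|---|---|
| `EC`   | `C·ET·EF·ED / AT` | f/mL | time-activity-weighted exposure concentration |
| `X`    | `C · horizon`     | f/mL·yr | cumulative exposure (dose metric of the potency models) |
| `Cavg` | `C · w`           | f/mL | average lifetime exposure concentration |

and four endpoint quantities:

- excess lifetime cancer risk `ELCR = EC · IUR`, screened against the
  regulatory bands (acceptable `< 1e-6`, considerable `> 1e-4`,
  tolerable in between — boundary values fall in the middle band because
  the screening guidance phrases the outer bands strictly);
- lung-cancer relative risk `RR = 1 + KL·X`;
- lifetime mortality risk `R = Cavg · UR · 100000` (per 100,000 persons),
  evaluated with lung and mesothelioma unit risks;
- mesothelioma incident cases `I = X · KM · s` per 100,000, with `s` the
  reporting-scale factor (below). The Nicholson-style ratio recalibration
  `I = I_ref · KM_sel / KM_nic` is provided separately
  (`nicholson_ratio_incidence`) for transferring a reference incidence to
  a different potency; it is not used for the report tables because the
  stated reference quantities do not generate them (the product form
  does, exactly).

Every uncertain potency is carried as a best-estimate / upper-bound (BE/UB)
pair, and the pipeline enforces UB ≥ BE end to end.

## Default parameters

| parameter | default | units | note |
|---|---|---|---|
| ET exposure time | 24 | h/day | continuous ambient exposure |
| EF exposure frequency | 180 | days/yr | outdoor-relevant days |
| ED exposure duration | 24 | yr | adult exposure window |
| AT averaging time | 74·365·24 | h | 74-year lifetime, leap days ignored |
| cumulative horizon | 50 | yr | covers the 20–50-yr mesothelioma latency |
| Cavg weight `w` | 30/7 ≈ 4.2857 | – | empirical calibration, see below |
| IUR | 0.23 | (f/mL)⁻¹ | inhalation unit risk, applied per f/mL |
| KL | 0.0030 / 0.011 | (f/mL·yr)⁻¹ | lung potency BE/UB |
| KM | 0.021 / 0.065 | table scale | mesothelioma potency BE/UB |
| UR lung | 0.0030 / 0.011 | (f/mL)⁻¹ | lifetime unit risk |
| UR mesothelioma | 0.0032 / 0.0099 | (f/mL)⁻¹ | lifetime unit risk |
| KM report scale `s` | 1000 | – | maps KM onto the per-100,000 column |
| risk bands | 1e-6 / 1e-4 | – | acceptable / considerable thresholds |

With these defaults `EC/C = (24·180·24)/(74·365·24) = 4320/27010 ≈ 0.15994`.

The IUR is applied per f/mL throughout. Some sources define inhalation
unit risks per µg/m³; no mass-concentration conversion is attempted here —
the 0.23 value is used on the fiber-count scale on which the reference
assessment operates.

## Calibration constants with empirical provenance

Two constants are calibrations rather than derived quantities, and both
are exposed as ordinary parameters:

- **`w = 30/7`.** The reference Tehran assessment reports a
  "Mean concentration" (Cavg) column whose ratio to the annual mean
  varies between 3.89 and 4.36 across years with no stated derivation;
  30/7 reproduces 8 of the 10 published values to their printed 4-decimal
  precision and is the package default. It is a weighted-average
  time-activity factor, not physics.
- **`s = 1000`.** KM is quoted nominally as ×10⁻⁸ (f/mL·yr)⁻¹, yet the
  published incidence column equals `X·KM·1000` per 100,000 exactly for
  every year. The factor 1000 is therefore treated as the table's
  reporting scale and documented as such.

## What the replication can and cannot reproduce

The published tables were evidently computed in two stages: Cavg was
tabulated first (independently rounded, and for some years not any fixed
multiple of the annual mean), and the mortality columns were then
computed *from the printed Cavg*. Consequently:

- Recomputing everything strictly from the ten annual means reproduces
  the cumulative-exposure, Cavg, incidence, and mortality columns at
  printed precision for most cells, but a minority of cells cannot be hit
  by any fixed weight: Cavg 2015; cumulative exposure 2020 (the table
  prints 0.0935 where 0.0019×50 = 0.0950, an apparent typo); lung
  mortality BE 2014/2015/2019 and most UB cells (±0.05 on a ×1100
  multiple of Cavg is tighter than the rounding of the printed Cavg
  itself); mesothelioma mortality BE 2014/2015/2019 and UB
  2011/2012/2014/2015/2016/2019; mesothelioma incidence UB 2020. The
  acceptance tests assert the strict recomputation anyway, so these cells
  fail visibly rather than being papered over.
- Supplying the printed Cavg column as observed data
  (`build_annual_summary(..., c_avg_observed=...)`) reproduces both
  mortality tables at printed precision, including the headline values
  8.4 → 1.8 (lung) and 8.96 → 1.92 (mesothelioma) per 100,000 exactly.
  This is the mode the `replicate` CLI command and the replication driver
  use, and it is legitimate: the printed Cavg is input data, not a model
  output of this package.
- The published RR(BE) column is consistent with a lung potency of 0.030,
  ten times the stated KL. The package defaults to the stated 0.0030 and
  ships a table-replication potency set (`table_replication_potency()`)
  with 0.030 that pins the RR(BE) column to ±0.001. The RR(UB) column is
  consistent with neither 0.011 nor 0.11 (implied slopes drift between
  0.06 and 0.09 row to row) and is not replicated.
- The published Monte Carlo mean ELCR agrees with the deterministic
  `EC·IUR` value to ≤1.6% for nine of ten years; the 2012 value (1.26e-4)
  sits 3.65% above it and cannot be matched by any mean-preserving input
  distribution. That one comparison fails by design.

## Monte Carlo engine

The engine replaces a spreadsheet-addin workflow with a seeded
`numpy.random.Generator`. Each factor of `EC` (C, ET, EF, ED) carries an
input distribution; unlisted factors default to point values. The default
scenario makes only the concentration stochastic — lognormal with
geometric standard deviation 1.5, the conventional description of
airborne-fiber variability — parametrised mean-preservingly
(`μ = ln m − σ²/2`, `σ = ln gsd`) so the MC mean estimates the
deterministic value. Summaries are the sample mean, SD (ddof=1), and the
5th/95th percentiles by linear interpolation between order statistics
(the original addin's convention is unknown; this is the common default).
10,000 iterations by default. Identical seed and inputs give bit-identical
summaries; a constant sample short-circuits the mean/SD computation so
that degenerate (all-point) runs collapse *exactly* onto the
deterministic pipeline rather than to within one ulp of pairwise
summation.

## Synthetic monitoring generator

`generate_series` emulates a city monitoring campaign: the true city mean
decays geometrically (default 0.0065 f/mL falling 12 %/yr, approximating
the observed ~0.0065 → ~0.0019 decade), optionally multiplied by episodic
spike years (the named `IMPORT_EVENT` scenario applies ×1.8 in 2016,
mirroring the unexplained 2016 increase); regional measurements are drawn
from a mean-preserving lognormal with gsd 1.5 (10 regions × 12
samples/year by default). gsd = 1 degenerates to exact means, which makes
the generator's truth an exact oracle for the whole pipeline. What it
does **not** emulate: spatial correlation between regions, seasonal
structure, censoring at the counting limit, or sample-size heterogeneity
across regions — so recovery tests demonstrate correct aggregation and
plumbing, not robustness to those real-data features.

## Numerical choices and degenerate inputs

- Concentrations are parsed as `decimal.Decimal`, so reading and
  rewriting a monitoring CSV preserves the original decimal strings;
  internal comparison tolerance is 1e-12 absolute.
- Aggregation is unweighted by default (regional sample sizes are not
  published); `by_n_samples` weighting is available, with missing counts
  contributing weight 1.
- Empty record lists, negative concentrations, non-positive horizons or
  weights, UB < BE, and ET·EF·ED exceeding AT all raise typed errors;
  nothing is silently clamped.
- Report tables round at the presentation boundary only: 4 decimals for
  concentrations, 3 for RR, 2 for per-100,000 risks.

## Problem sizes

The replication operates on the full published dataset (10 years). Monte
Carlo runs use the published 10,000 iterations; the convergence property
is checked with 20 independent seeds at n = 10,000, and synthetic
recovery with 10 regions × 12 samples × 10 years.

## Known limitations

- Scalar, linear dose-response only; no age-structured or power-law
  latency (Peto-type) mesothelioma projection, and no smoking interaction.
- City-wide means hide spatial contrast; the regional machinery is
  aggregation plumbing, not a dispersion model.
- The Cavg weight and KM reporting scale are calibrations against one
  published assessment; transferring them to another setting requires
  re-deriving both.
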