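# Methods

## Model structure and assumptions

The simulator is a deterministic system-dynamics model with two patient
stocks (occupants of public and private hospitals), one behavioural state
(the insurance penetration `HI`), and two Erlang-3 delay cascades.  Its core
assumption is a balancing feedback loop: inpatient bed occupancy is the
crowdedness proxy for each sector (it is the only such metric observable for
both sectors in Hong Kong), and only the occupancy *gap* between the sectors
— not public crowdedness alone — drives insurance demand, because crowding
matters only when a less crowded private alternative exists.  The demand
effect is absolute: `HI` is the baseline penetration plus the delayed gap
effect plus, after the tax-incentive scheme starts, a delayed tax effect.

Further assumptions inherited from the model design:

- Admission splitting treats the insured/uninsured shares of inpatients as
  equal to the population shares.
- Private length of stay is `PuLoS × SeverityFtr`; the severity adjustment
  absorbs the observation that private hospitals treat lighter cases.
- Occupancy uses the flow form `admissions × LoS / beds` (Little's law
  applied to the daily admission rate).  A stock-based form
  (`occupants / beds`) is available via `occupancy_basis="stock"`; the two
  agree at equilibrium and differ during transients such as the winter
  surge.
- Discharge outflow is `stock / LoS` (first-order).  A verbal description
  of discharges as "admissions divided by length of stay" is dimensionally a
  flow only in steady state; the stock/LoS form reproduces exactly that
  steady state and is used throughout.
- The occupancy gap is oriented public-minus-private, so a public sector
  busier than the private one yields a positive demand effect.  This is the
  orientation under which the loop is balancing and under which a higher
  severity adjustment lowers final penetration.  The printed
  private-minus-public convention is available via `diff_orientation`.
- No outpatient care, no explicit waiting-time queues, no disenrollment
  dynamics beyond the symmetric (sign-reversible) gap effect.

## Demand profile

Annual series are step functions over their labelled year: fiscal
(Apr 1–Mar 31) for admissions, public length of stay and public beds,
natural for private beds — matching how the source statistics are reported.
Linear interpolation between period-start anchors is available as an option
(`interpolate=True`).

The winter surge spans 90 days: a 30-day linear ramp from the non-surge
level starting December 16, a 30-day plateau at `peak_ratio` (1.196×)
over January 15–February 13, and a 30-day linear ramp down.  Daily sampling
is chosen so that the samples over a calendar year sum *exactly* to the
closed-form annual total `(days−90)x + 30rx + 2·30·(x+rx)/2`: the up-ramp
samples start at the non-surge level on December 16, while the down-ramp
samples start at the peak level on February 14 and reach the non-surge level
the day after March 15.  In leap years the extra day is a non-surge day.
The whole surge window falls inside a single fiscal year, so no year
blending is needed.

## Delays and integration

The perception delay is a third-order exponential (Erlang-3) material
delay: three cascaded first-order stages with time constant `Duration/3`
(`Duration` = 365 days).  Integration is explicit Euler at `dt` = 1 day,
matching the simulation platform convention the model was originally built
under; at this step the delay's unit-step response tracks the Erlang-3
closed form `1 − e^{−t/τ}(1 + t/τ + (t/τ)²/2)` to 0.16% at `t = Duration`,
and the constant-input fixed point is preserved exactly.  `dt` is
configurable for convergence checks; sub-daily records are emitted only on
request.

Delay initialisation is not observable from published output.  The default
(`delay_init="match"`) sets the occupancy-effect cascade to the fixed point
of its first input, so the feedback starts at its instantaneous level — the
documented "initiation jump" of the first simulated years, which is treated
as warm-up and excluded from evaluation.  `delay_init="zero"` starts the
cascade empty.  The tax-effect cascade always starts empty with zero
pre-policy input, making the effect exactly zero before the 2019-04-01
activation.

Numerical details: stocks are floored at zero; `HI` is clipped to [0, 1];
the structural variant `clamp_effect_nonneg` floors the occupancy effect at
zero before the sum (both variants are searched during calibration, ties
breaking to the plain form).  Admission splitting uses a double complement
(`pu = n − pr; pr = n − pu`) so that public + private admissions equal the
demand bit-exactly (Sterbenz's lemma guarantees one of the two subtractions
is exact).

## Parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| `use_hi` | 0.57 | fraction | insured patients who go private |
| `selfpay` | 0.06 | fraction | uninsured patients who pay privately |
| `severity_ftr` | 0.39 (calibrated; 0.4 pre-calibration) | ratio | private LoS / public LoS |
| `occu_dmd` | 0.5 (calibrated; 1.3351 pre-calibration) | 1/occupancy | gap-to-demand elasticity |
| `tax_dmd` | 0.138 | — | tax-saving-share-to-demand elasticity |
| `baseline_diff` | 0.055 | occupancy | reference occupancy gap |
| `baseline_hi` | required | fraction | penetration at horizon start |
| `delay_duration` | 365 | days | perception delay |
| `surge_peak_ratio` | 1.196 | ratio | winter peak vs non-surge demand |
| Tax policy | 8000 / 0.85 / 0.06 / 2876 | HKD, fractions | cap, premium ratio, rate, avg tax |

The published tables list the severity adjustment both at 0.4 (literature)
and 0.39 (calibrated); the bundle ships the calibrated 0.39, with the
pre-calibration values retained in `params.PRE_CALIBRATION`.

`baseline_hi` is deliberately *not* bundled: the 2009 survey value is not
part of the published point estimates.  `calibrate.fit_baseline_hi`
recovers it by bounded scalar MAPE minimisation against a reference series;
on the three bundled survey points it yields 0.2258.  Note this baseline is
a model quantity (penetration net of the steady-state feedback effect), not
the raw 2009 survey share.

With that fitted baseline the simulation reproduces the published
trajectory and band closely; the published last-5-year MAPE of 0.94% was
computed against the full multi-survey reference series, of which only
three points are bundled here, so MAPE values computed from the bundle are
not directly comparable to it (on the bundled points the in-window MAPE is
0.19%).

## Calibration

Goodness of fit is the mean absolute percentage error between simulated and
surveyed penetration at the survey dates inside the evaluation window
(2015-01-01 to 2019-12-31 by default).  The simulated counterpart of a
survey point is the value on the survey's exact date; averaging over the
fieldwork year is available (`aggregation="year_mean"`) since no aggregation
rule is prescribed.  Calibration enumerates a user-supplied grid over
`severity_ftr × occu_dmd × {plain, clamp_nonneg}` and keeps the smallest
MAPE, ties breaking to the first combination in lexicographic grid order.
Default grids (severity 0.35–0.43 step 0.01; elasticity 0.1–1.4 step 0.05)
cover both the literature-derived starting values and the calibrated
optimum.

## Sensitivity analysis

Parameters bounded in [0, 1] are sampled from Beta distributions whose
shapes derive from the published mean and a symmetric ±10% range read as
mean ± 2 sd (`beta_params_from_range`); the unbounded elasticity from
Normal(0.5, 0.025).  Each of the 500 runs (seed 1234) draws one constant
parameter set — the uncertainty is in the constants, not in daily noise —
and percentile curves (2.5/25/50/75/97.5) are taken pointwise across runs.
Draws are independent Monte Carlo; the original platform's noise stream is
not reproducible outside it, so comparisons are made on percentile bands,
never per-run values.

## Synthetic scenarios and what passing tests show

`scenarios.generate_scenario` builds fully synthetic systems with the
structure the model assumes: geometric growth in admissions and beds, a
surge at exactly the configured peak ratio, and survey observations equal
to the simulated penetration plus additive Gaussian noise clipped to [0, 1].
It does not emulate demographic structure, reporting bias, policy breaks or
demand shocks — so recovery results certify the *estimation machinery*
(that the calibration procedure finds generating parameters when the model
is true), not robustness to misspecification on real data.

The bundled recovery study uses a scenario with diverging sector capacities
(private beds +4.5%/yr vs public +1.5%/yr, mirroring the Hong Kong
2014–2019 pattern) and a monthly survey panel over 2011–2016.  This design
matters: the severity adjustment and the demand elasticity trade off along
a near-degenerate ridge of the MAPE surface when the occupancy gap is
static or surveys are sparse, because both parameters scale the effect term
in nearly the same way.  A trending gap and a dense panel separate them.
The recovery grid (severity step 0.04, elasticity step 0.2) keeps
neighbouring cells at least ~1 pp rms apart in fitted space; with 0.5 pp
survey noise the generating cell is recovered within one neighbour in all
50 seeded replicates, degrading gracefully at 2 pp noise.

## Problem sizes used in the test suite

The full Hong Kong horizon (2009-04-01 to 2019-12-31, 3927 daily steps) is
simulated directly throughout; the Monte-Carlo reproduction uses the full
500 runs; the recovery study uses 8-year scenarios, a 5×5 grid and 50
replicates per noise level.

## Known limitations

- The occupancy gap implied by the published inputs (~30 pp) is far above
  the 5.5 pp reference gap, so the feedback effect is large and the fitted
  `baseline_hi` is correspondingly below the surveyed 2009 penetration; the
  sourcing of the 5.5 pp value cannot be reconstructed from the published
  equations.  Both `baseline_diff` and `baseline_hi` are therefore free
  calibration inputs.
- Whether the published runs used the clamped structural variant is not
  stated; the default is the plain form, and on the bundled inputs the two
  coincide (the gap effect never goes negative).
- Survey reference data bundled with the package is the three-point subset
  quoted in public text; conclusions that need the full survey panel (such
  as recomputing the published 0.94% MAPE) are out of reach.
- The model is explanatory, not predictive: coincident feedback terms fit
  history well but provide no out-of-sample guarantees, and COVID-era
  dynamics are outside its scope.
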