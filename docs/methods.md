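# Methods

## Model

`patchpk` treats the body as one well-mixed plasma compartment per
hormone. The serum concentration *C* of each active ingredient of the
patch — norelgestromin (NGMN, ng/mL) and ethinylestradiol (EE, pg/mL) —
obeys

    dC/dt = f(t) · (k_o / V_d) · exp(−a · s(t)) − k_elim · C

The first term is absorption from the patch. `k_o` is the release rate
of a fresh patch and `V_d` the apparent volume of distribution, so
`k_o / V_d` is the initial absorption rate in concentration units per
unit time. The exponential in patch age `s(t)` lumps every mechanism
that progressively attenuates delivery — depletion of hormone in the
reservoir, saturation of the stratum corneum, adhesive aging — into one
constant `a` (α for NGMN, β for EE); no attempt is made to resolve
skin-layer diffusion. `f(t)` scales absorption by the attached area
fraction, which is how partial detachment enters. The second term is
first-order elimination. The model is linear in the input, so
trajectories scale exactly with `k_o` and with `f`.

The patch age resets when a patch is replaced or a new one is applied;
pressing the *same* patch back after a partial detachment does not reset
it, because that patch has kept aging. Whether a post-detachment
reapplication is "same patch" or "new patch" is genuinely ambiguous in
practice, so the detachment scenario constructor exposes both
(`reattach_vs_new`); after a 24 h *total* detachment the default builder
uses a new patch, matching the manufacturer's instruction to apply a
fresh one.

## Solvers

Two solvers share the regimen/segment machinery:

* **Forward difference** (`simulate_difference`) — the explicit Euler
  scheme the model is naturally written in for discrete clinical data:
  `C(t+Δt) = C(t) + [R_abs(t) − k_elim·C(t)]·Δt`, default `Δt = 0.1 h`.
  First-order accurate; a step that would drive the concentration
  negative (only possible for `k_elim·Δt > 1`, far outside the
  physiological range at `Δt ≤ 1 h`) raises an instability error rather
  than clipping silently. Sub-epsilon negative round-off is clipped to
  zero with a logged warning.
* **Piecewise closed form** (`simulate_analytic` /
  `analytic_concentrations`) — between wear events the ODE is linear
  with exponential forcing and solves exactly:
  `C(t₀+τ) = C(t₀)e^{−kτ} + f·(k_o/V_d)·e^{−a·s₀}·(e^{−aτ} − e^{−kτ})/(k − a)`.
  When `|k − a|` falls below a relative tolerance of 1e-10 the confluent
  limit `f·(k_o/V_d)·e^{−a·s₀}·τ·e^{−kτ}` is used instead of dividing by
  `k − a`.

The closed form is the accuracy oracle: over the standard three-week
NGMN cycle the two agree to 3.6e-4 ng/mL at `Δt = 0.1 h`, and the
deviation halves when the step halves, as a first-order scheme must.

## Parameters

Published constants ship as presets; all internal time is in hours, and
per-day printed values (`k_o`, α, β) are divided by 24 on ingestion.

| quantity | NGMN | EE | unit |
|---|---|---|---|
| k_o | 150 | 20.5 | µg/day |
| Cl | 7.89 | 18.3 | L/h |
| t_1/2 | 28.4 | 15.2 | h |
| k_elim | 0.0244 | 0.0385 | 1/h |
| V_d | 323,300 | 401,385 | mL |
| α, β (printed) | 0.0028 | 0.0034 | see below |
| effective band | 0.6–1.2 ng/mL | 25–75 pg/mL | |

Three presets: `table1-verbatim` (default, the constants exactly as
printed), `halflife-consistent` (k_elim recomputed as ln2/t_1/2 and V_d
as Cl/k_elim), and `updated-k0` (manufacturer-updated release rates of
200 and 35 µg/day). The printed EE row is internally inconsistent —
0.0385/h does not equal ln2/15.2 h = 0.0456/h, and the printed V_d
matches Cl divided by the *half-life-implied* constant — so `DrugParams`
carries an `is_consistent` flag (2% relative tolerance) instead of
silently reconciling; the verbatim preset keeps the printed numbers and
flags the EE row.

### The absorption-attenuation time unit

The printed α and β carry no unit, and no single reading reproduces
every published result:

* Read **per day** (the package default, 0.0028/24 per hour for NGMN),
  absorption attenuates only ~6% over a 504 h cycle. This reproduces the
  published model-fit predictions for the standard cycle — plateau
  0.773 ng/mL (we compute 0.785) and mean weekly AUC 123.40 ng·h/mL
  (121.2) for NGMN; 52.63 pg/mL (54.6) and 8463.75 pg·h/mL (8708) for EE
  — all within 4%. Read per hour, the week-long plateau collapses
  (NGMN plateau 0.632, −18%).
* Read **per hour**, the non-compliance findings emerge: with a
  replacement delayed from day 14 to day 17, NGMN dips below its
  0.6 ng/mL floor around day 16 while EE stays in range — exactly the
  published scenario narrative. Under the per-day reading the extended
  wear costs <3% of absorption and NGMN never dips.

These are mutually exclusive, so the unit is exposed as an ordinary
configurable (`decay_const` in 1/h, or `decay_const_per_day` in run
configs). Defaults use per-day, which anchors the quantitative
steady-state targets; the delayed-replacement scenario test evaluates
the qualitative day-16 finding under the per-hour reading and says so.
Scenario *window durations* (the published 14/22/26/34 h grace periods)
are treated as ordering properties only — later-week detachments give
longer grace than week-1 detachments, and earlier week-1 detachments
give shorter grace — never as numeric targets.

## Metrics

* `css` — trapezoidal time-average over a window. The plateau window
  defaults to the third wear week (hours 336–504), when the weekly
  pattern is fully established; the source never states its averaging
  convention, so this is a package choice and is configurable.
* `auc` — trapezoidal integral with linearly interpolated window edges;
  exactly additive over abutting windows. Weekly AUCs are reported per
  week and as the mean over the three-week cycle; the mean is the value
  compared against the published weekly-AUC prediction (which does not
  state its week convention either).
* `range_crossings` — the trajectory is treated as the piecewise-linear
  interpolant of the grid (consistent with the first-order solver);
  threshold crossings are located by linear interpolation, and the span
  partitions exactly into below-band (pregnancy-risk), in-band, and
  above-band intervals.

## Estimation

* `k_elim`: unweighted ordinary least squares of ln C on t over
  post-removal samples (the terminal-slope method). Unweighted because
  the assumed noise is multiplicative lognormal, which is homoscedastic
  on the log scale. Non-positive concentrations are a domain error, not
  a droppable point.
* α/β: bounded scalar least squares (Brent-style, `xatol = 1e-12`,
  deterministic) of observations against the closed-form trajectory over
  `[0, 10×]` the preset value, everything else fixed — it is the model's
  only adjustable parameter. A boundary optimum is flagged
  `converged = False`. Duplicate observation times are allowed and
  treated as independent observations.
* `V_d = Cl/k_elim` and `t_1/2 = ln2/k_elim` reproduce the published
  volumes to 0.1% when k_elim is taken from the half-life.

**Identifiability.** At a 5% assay CV the attenuation constant is only
recoverable when it moves the trajectory by more than the noise floor.
With the per-day default (total attenuation ~6% per cycle) a 20-point
fit misses the generating value by a median 77% across seeds — the
parameter is structurally unidentifiable at that noise level, which is a
property of the design, not the optimiser. The noisy-recovery tests
therefore generate data from the per-hour-scale variant (attenuation
e^(−0.47) per week), where recovery lands within 11% for every seed
tried; the noiseless self-consistency test recovers the per-day value to
<1%.

## Synthetic data

`generate_observations` evaluates the closed-form model at the design's
sampling times and multiplies by i.i.d. lognormal noise with mean 1 and
CV `noise_cv` (σ² = ln(1+cv²), µ = −σ²/2), seeded through
`numpy.random.default_rng` for bit-identical reproducibility. Default
CV 0.05 (proportional assay error on positive concentrations); default
schedule every 12 h while the patch is worn, every 6 h in the
post-removal decay. The generator emulates a *single individual*
sampled sparsely: it deliberately omits between-subject variability,
within-subject kinetic drift, assay quantification limits, and sampling
jitter — so passing recovery tests demonstrate estimator correctness
under the model's own assumptions, not performance on population data.

## Problem sizes and numerical choices

Default simulations integrate 600 h at `Δt = 0.1 h` (6001 points,
milliseconds); the solver cross-check uses `Δt = 0.01 h`. Recovery
tests use 12–20 observations, matching sparse clinical sampling; the
noise-calibration check uses 1000 single-point replicates. CSV output
is fixed at 6 significant digits, which makes repeat runs byte-identical
across platforms.

## Limitations

One compartment, linear kinetics, a single lumped exponential for
absorption: no skin-depot PDE, no metabolite kinetics, no
pharmacodynamics (ovulation or pregnancy probability), no population
variability. The published parameter table's internal inconsistencies
(EE k_elim vs half-life; the α/β unit) are surfaced, not resolved —
conclusions that depend on the attenuation unit should be checked under
both readings, as the scenario tests do.
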