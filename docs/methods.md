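# Methods

## The experiment being modelled

Three inert rubber corneal phantoms, calibrated by the tonometer
manufacturer to behave like eyes at 6, 13 and 43 mmHg intraocular
pressure (IOP), are mounted in a foam headform and measured with a
noncontact tonometer while a consumer air-quality indicator (AQI) records
PM2.5 and PM10 mass concentrations at four positions (upper/lower ×
same/opposite side relative to the tested eye).  Each of the 12
(phantom × location) cells is tested four times; every test records a
baseline reading before the puff and a reading during it, giving
3 × 4 × 4 × 2 = 96 readings.  The phantoms contain no liquid, so the true
aerosol signal is exactly zero: the design is a negative control for the
claim that AQI readings during tonometry measure tear-film
aerosolization.

The analysis quantity is ΔPM = during − baseline per test and channel.
Deltas may be negative and are kept signed; raw readings are physical
concentrations and are clipped at zero.

## Synthetic-data generator

The generator reproduces the experiment's statistical structure rather
than its aerodynamics.  Per cell and channel, ΔPM ~ Normal(mean, sd) with
the cell's observed mean and sample SD (the packaged `table1_noise_model`
carries the study's printed 24 cells); the during reading is the baseline
plus that draw.  Choices that the source data do not constrain, fixed
once here:

* **Gaussian noise on the delta.**  Only means and SDs are reported, and
  the study's own Monte Carlo uses exactly these as Normal parameters;
  the Gaussian is the minimal consistent model.
* **Baselines.**  Baseline level and spread are not reported beyond
  readings being "around 1–3 µg/m³"; baselines draw from
  Normal(2.0, 0.3) µg/m³ per channel, independent of the delta.  Because
  the analysis subtracts baselines, these defaults affect nothing
  downstream except the (rare) zero-clipping of raw readings.
* **Clipping.**  Raw readings are clipped at 0 (a mass concentration
  cannot be negative); deltas are not (the observed table has negative
  cells).  With the default baseline level, clipping events are ~3σ
  tail events and introduce negligible bias (< 10⁻⁴ µg/m³ per cell).
* **Seeding.**  A master seed spawns one substream per (IOP, location)
  cell in canonical order, so the draw a cell receives does not depend on
  generation order or on which other cells exist.

What the generator does *not* emulate: display quantization of raw
readings (available only as an explicit write-time option), temporal
drift, autocorrelation between consecutive tests, and any puff-driven
airflow physics.  Passing tests therefore show that the *statistical
pipeline* behaves correctly under the study's own noise model — not that
the model captures every feature of the real instrument.

## Summaries

Per (IOP, location, channel): n, sample mean, and sample SD with the n−1
denominator.  With n = 4 the n vs n−1 choice is material; n−1 matches the
usual "mean ± SD of four tests" convention and is what makes the
summary-statistics ANOVA reconstruct the raw-data ANOVA exactly.  SD is
undefined (NaN) for singleton cells.  Rounding to the display precision
(0.1 µg/m³) happens only in rendered reports, never in stored values.

## Two-way ANOVA

Both factors are categorical; the design is balanced, so factor sums of
squares are orthogonal and Type I/II/III coincide.  The default model is
main effects only (IOP + location): the study reports exactly one
p-value per factor and never mentions an interaction.  The
`with_interaction` model (df 6) is available for sensitivity analysis; on
the printed table it gives p_interaction = 0.49 and leaves the factor
conclusions unchanged.

The summary path uses the balanced-design identities: factor SS from cell
means, within-cell SS = Σ (n−1)·sd².  Equivalence with the raw path is
property-tested to 1e-9 relative SS difference, and both are checked
against statsmodels' `anova_lm` as an independent reference.  F tail
probabilities come from `scipy.stats.f`.  Degenerate inputs (zero
residual mean square) flag F and p as NaN rather than dividing by zero.

On the study's printed cells (n = 4) the main-effects model gives
PM10: p_IOP = 0.0400, p_location = 0.0119 (both < 0.05);
PM2.5: p_IOP = 0.2435, p_location = 0.2806 (both > 0.05) — the published
qualitative pattern.  The published p-values themselves (0.0241, 0.0167,
0.3943, 0.3049) are not recovered: the printed table is rounded to one
decimal and the original model specification (interaction? IOP numeric or
categorical? software defaults?) is unstated, so exact reproduction is
not promised; the computed values above are what the printed table
supports.

## Monte Carlo spurious-trend estimator

Inputs are the three per-phantom (mean, sd) pairs of one location and
channel.  Each of R = 10,000 replicates draws k simulated ΔPM values per
phantom and evaluates a trend of value on IOP (numeric mmHg 6/13/43 by
default; ranks available).  The estimate p̂ is the fraction of replicates
with a positive trend; its Monte Carlo SE is √(p̂(1−p̂)/R).  A slope of
exactly zero counts as *not* positive (measure-zero under Gaussian
noise).  Replicate draws use per-variant substreams derived from the
master seed, making every result bit-reproducible.

Because the source defines neither the trend criterion nor the simulation
unit, the estimator exposes a variant grid:

* criterion: slope sign (default, the most parsimonious reading),
  Pearson sign (identical in sign to the slope; kept explicit), or
  significant-and-positive slope at α = 0.05;
* draws per phantom k: 4 (the experiment's repeat count) or 1 (a single
  simulated estimate per phantom);
* draw scale: the cell SD (simulating individual tests) or the standard
  error of the mean sd/√4 (simulating the reported per-cell mean).

For the sign criterion the exact answer is available in closed form —
the OLS slope is a linear combination of independent Gaussians, so
P(slope > 0) = Φ(E[slope]/SD[slope]) — and the MC estimator is tested
against it on randomized configurations.

**Sensitivity at the upper-same location** (analytic values): PM2.5 —
53.4% (k=1, SD), 56.8% (k=4, SD, equivalently k=1 SEM), 63.4% (k=4,
SEM); PM10 — 65.0%, 77.9%, 93.8% for the same variants.  The published
53% (PM2.5) is matched by the single-draw/cell-SD variant; the published
92% (PM10) is bracketed, with the k=4/SEM variant closest (93.8%).  No
single variant reproduces both published figures, which is itself a
finding about the under-specification: the qualitative conclusion —
PM10's spurious-trend probability is far above PM2.5's and far above 50%
— holds across all variants, and the package reports the full grid rather
than presenting one variant as the reconstruction.

## Sensor-limits model

`flag_below_accuracy` marks cells whose |mean ΔPM| is below the channel's
nominal accuracy half-width (±10/±15 µg/m³); all 24 observed cells are
flagged, i.e. every reported change is inside the instrument's own error
band.  `window_response` models the 3 s update interval as a
time-averaging window: a pulse of duration d ≤ 3 s is attenuated by its
duty factor d/3 (× ½ for a triangular pulse), so the nominal 30 ms puff
is attenuated 100-fold; optional quantization applies the 0.1 µg/m³
display step after averaging.  Whether the real device integrates over
the window or samples-and-holds is undocumented; the time average is one
defensible choice and is labelled as such.  The phantom IOPcc calibration
table is packaged as a fixture with a simple agreement check (ordering
preserved, |mean − nominal| ≤ 2 mmHg) only.

## Numerical and testing choices

* Problem sizes: parameter-recovery checks run the generator at 10,000
  tests per cell (480,000 readings, a few seconds) and compare each of
  the 24 cells' mean/SD to the noise model within 3 standard errors.
  With 48 simultaneous 3-SE comparisons a correct generator still has a
  ≈12% chance of one excursion per seed; the fixed test seeds make the
  check deterministic.
* Monte Carlo checks use 10,000 replicates (matching the study) for
  headline quantities and 4,000 for randomized property tests.
* Equality tolerances: summary-vs-raw ANOVA at 1e-9 relative SS;
  p-values vs the reference implementation at 1e-10 absolute.
* CSV round-trips write floats with `%.17g` and parse with pandas'
  round-trip parser, so stored tables are lossless.

## Known limitations

The package analyses the measurement technique, not aerosol physics: it
cannot say whether tonometry generates aerosols, only that this AQI — by
its noise level, accuracy band and update rate — cannot detect them.  The
Gaussian cell model ignores any dependence between channels (PM2.5 and
PM10 share hardware and are certainly correlated in the real device);
this does not affect per-channel analyses.  The ANOVA contract covers
balanced designs only, matching the experiment; unbalanced data are
rejected rather than approximated.
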