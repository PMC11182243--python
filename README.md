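# puffnull

**Can a consumer air-quality indicator detect aerosol generation during
noncontact tonometry? A negative-control analysis says no.**

Noncontact tonometry (NCT) estimates intraocular pressure (IOP) with a
~30 ms air puff.  During the COVID-19 pandemic, studies placed a consumer
air-quality indicator (AQI, a light-scattering PM2.5/PM10 sensor) next to
patients' eyes, observed IOP-correlated increases in reported particulate
matter, and concluded that NCT aerosolizes the tear film.  `puffnull`
implements the negative-control analysis that tests this measurement
technique itself: the same experiment run on *dry rubber corneal phantoms*
(IOP equivalents 6, 13, 43 mmHg) that cannot generate aerosols.  Any
IOP- or location-dependent structure in the AQI readings is then, by
construction, an instrument artifact.

The package is aimed at measurement-validity and reproducibility work in
biostatistics: it provides the experiment simulator, the summary
statistics, the ANOVA, the Monte Carlo false-positive estimator and the
sensor-physics model as reusable, tested components.

## What it computes

With ΔPM = (during-puff reading) − (baseline reading), per phantom *i* and
sensor location *j*:

* **Cell summaries** — mean ± sample SD (n−1) of ΔPM2.5/ΔPM10 over the
  n = 4 repeated tests per (IOP, location) cell.
* **Balanced two-way ANOVA** — y<sub>ijk</sub> = µ + α<sub>i</sub> +
  β<sub>j</sub> + ε<sub>ijk</sub> (optionally with interaction), computed
  from orthogonal sums of squares either from raw records or *from the
  per-cell summaries alone*, using SS<sub>within</sub> = Σ (n−1)·sd² —
  so a published mean ± SD table is sufficient input.
* **Monte Carlo spurious-trend probability** — with no true signal, draw
  simulated ΔPM per phantom from Normal(mean<sub>i</sub>, σ<sub>i</sub>)
  (the observed cell statistics), fit the OLS trend of ΔPM on IOP
  (6/13/43 mmHg), and estimate p̂ = P(positive trend by chance) over
  10,000 replicates, with Monte Carlo SE √(p̂(1−p̂)/R).  Because "a
  positive correlation" is operationally ambiguous, a variant grid
  (slope sign / Pearson sign / significant positive slope × draws per
  phantom × cell-SD vs SEM draw scale) is provided, plus the exact
  closed form P(slope>0) = Φ(E[slope]/SD[slope]) for cross-checking.
* **Sensor limits** — every observed |ΔPM| is far below the device's
  nominal accuracy (±10 µg/m³ PM2.5, ±15 µg/m³ PM10), and a 30 ms puff
  time-averaged over the 3 s update window is attenuated by its duty
  factor 1/100 before it can be displayed.

## Worked example

```python
import puffnull as p
from puffnull.synthetic_data import TABLE1_DELTA_STATS

# the study's printed per-cell results (24 cells, n=4 each)
cells = [p.CellSummary(iop, loc, ch, 4, m, s)
         for ch, by_loc in TABLE1_DELTA_STATS.items()
         for loc, by_iop in by_loc.items()
         for iop, (m, s) in by_iop.items()]

print(p.anova_from_summary(cells, "pm10"))
```

```
Two-way ANOVA (main_effects) on delta PM10
source        df          SS          MS         F         p
iop            2      1.1400      0.5700    3.4780    0.0400
location       3      2.0267      0.6756    4.1220    0.0119
residual      42      6.8833      0.1639
total         47     10.0500
```

Both factors are *significant* (p < 0.05) for PM10 — on phantoms that
cannot emit aerosols — while the same analysis for PM2.5 gives p = 0.24
(IOP) and 0.28 (location), i.e. no effect.  The Monte Carlo estimator
quantifies how easily such trends arise from the observed noise alone:

```python
us = [c for c in cells
      if c.location is p.Location.UPPER_SAME and c.channel is p.Channel.PM10]
r = p.mc_spurious_trend(us, p.MCConfig(seed=0))
print(f"P(spurious positive PM10 trend) = {r.p_hat:.3f} +/- {r.mc_se:.4f}")
# P(spurious positive PM10 trend) = 0.779 +/- 0.0041

print(p.window_response(p.PulseEvent(duration=0.030, amplitude=250.0)))
# 2.5   <- a 250 ug/m3, 30 ms pulse reports as 2.5 ug/m3 in a 3 s window
```

A chance positive PM10 "correlation" at the location nearest the puff is
the *likely* outcome, and even a dense 250 µg/m³ transient would be
averaged down to 2.5 µg/m³ — below both channels' nominal accuracy.

The same pipeline runs end-to-end from the shell:

```sh
puffnull simulate --seed 1 --out meas.csv        # 96 synthetic readings
puffnull summarize --in meas.csv --out cells.csv --deltas-out deltas.csv
puffnull anova --in deltas.csv --channel pm10
puffnull mc --replicates 10000 --seed 1 --location upper_same
puffnull report --outdir run1                    # full CSV + text bundle
```

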