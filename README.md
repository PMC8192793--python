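# shortsprint

Sprint mechanical profiling from timing-gate split times.

Practitioners in team sports assess linear sprint ability with infrared
timing gates placed at a handful of distances (typically 5, 10, 20, 30 and
35 m). The cumulative split times can be turned into a mechanical profile of
the sprint — maximal speed, maximal acceleration, and the force–velocity–
power characteristics behind them — by fitting the mono-exponential model

```
v(t) = MSS · (1 − e^(−t/TAU))
```

where MSS is the maximal sprinting speed (m/s) and TAU the time constant
(s), the time needed to reach 63.2 % of MSS. Maximal acceleration is the
derived quantity MAC = MSS/TAU. Inverting the integrated velocity curve with
Lambert's W function gives the split time a gate at distance *d* records:

```
t(d) = TAU · W₀(−e^(−d/(MSS·TAU) − 1)) + d/MSS + TAU − tc
```

The correction `tc` matters because start-line gates trigger *after* first
force production; ignoring that lag inflates acceleration and force
estimates. `shortsprint` fits this model by bounded non-linear least squares
under the three regimes practitioners debate:

* **none** — no correction (tc = 0);
* **fixed** — a correction chosen a priori (default +0.3 s);
* **estimated** — tc estimated jointly with MSS and TAU.

On top of the fit it derives the force–velocity profile (F0, V0,
Pmax = F0·V0/4, FV slope = −F0/V0, RFmax, DRF) from body mass, stature and
an aerodynamic drag model, and compares regimes across a cohort with bias
tables, Cohen's *d* effect sizes and correlations. A synthetic-cohort
generator with realistic parameter distributions supports validation and
parameter-recovery studies.

## Worked example

```python
from shortsprint import SplitSet, compare_modes, compute_fv_profile, CorrectionMode

splits = SplitSet("athlete_mean", (5, 10, 20, 30, 35),
                  (1.20, 2.00, 3.39, 4.71, 5.36),
                  body_mass=62.3, stature=1.674)
fits = compare_modes(splits, fixed_correction=0.3)
for mode, fit in fits.items():
    p = fit.parameters
    print(f"{mode.value:9s} MSS={p.mss:.2f} m/s  TAU={p.tau:.3f} s  "
          f"MAC={p.mac:.2f} m/s²  tc={p.time_correction:+.3f} s")

prof = compute_fv_profile(fits[CorrectionMode.ESTIMATED].parameters, 62.3, 1.674)
print(f"F0={prof.f0_rel:.2f} N/kg  V0={prof.v0:.2f} m/s  "
      f"Pmax={prof.pmax_rel:.1f} W/kg  RFmax={prof.rf_max:.1f}%  DRF={prof.drf:.2f}")
```

prints

```
none      MSS=7.45 m/s  TAU=0.680 s  MAC=10.96 m/s²  tc=+0.000 s
fixed     MSS=7.84 m/s  TAU=1.201 s  MAC=6.53 m/s²  tc=+0.300 s
estimated MSS=7.75 m/s  TAU=1.107 s  MAC=7.01 m/s²  tc=+0.253 s
F0=6.94 N/kg  V0=8.01 m/s  Pmax=13.9 W/kg  RFmax=47.9%  DRF=-8.02
```

Read the contrast across rows: without a start correction the fit absorbs
the gate lag into a much smaller TAU, inflating MAC by over 50 %; the fixed
and estimated regimes agree closely, and the estimated lag (+0.25 s) lands
near the conventional fixed value.

A CLI wraps the same pipeline:

```
shortsprint simulate --n 50 --seed 7 --out cohort.csv
shortsprint cohort cohort.csv --out report/
```

which writes `parameters.csv`, `fv_profiles.csv`, `bias.csv`, `summary.csv`
and a run log.

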