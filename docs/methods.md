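# Methods

## The model

Short maximal sprints are described by a mono-exponential velocity curve
`v(t) = MSS·(1 − e^(−t/TAU))` with two parameters: the asymptotic maximal
sprinting speed MSS (m/s) and the time constant TAU (s). The model assumes a
single accelerative effort from a standing start on a straight track —
no bends, no fatigue, no wind adjustment. Acceleration is
`a(t) = (MSS/TAU)·e^(−t/TAU)`, so the maximal acceleration MAC = MSS/TAU is
attained at t = 0 and is the quantity of interest for acceleration ability
(TAU alone is only interpretable jointly with MSS). Integrating v(t) gives
the closed-form distance `d(t) = MSS·t − MSS·TAU·(1 − e^(−t/TAU))`; solving
that for t yields the split-time equation through the principal branch W₀ of
Lambert's W. Only W₀ is admissible: the argument `−e^(−d/(MSS·TAU)−1)` lies
in (−1/e, 0] for d ≥ 0, and the principal branch is the one that gives t = 0
at d = 0 and monotone times. At d = 0 the argument sits exactly on the
branch point −1/e, where the numeric W₀ evaluation is undefined; the code
substitutes the exact value W₀(−1/e) = −1. For `d/(MSS·TAU) > 700` the W₀
term underflows and is set to 0 (true magnitude < 1e−300 s).

## Time origin and the gate-lag correction

Internal model time runs from first force production. A start-line gate
triggers only once the athlete's body crosses the beam, a lag `tc` after
first force production, so gate-clock time = model time − tc. All public
split-time operations are in gate-clock time; consequently
`time_at_distance(p, 0) = −tc`, a legitimately negative reading meaning the
athlete moved before the clock started. The correction can be absent
(tc = 0), fixed a priori (+0.3 s by default, appropriate when the athlete
starts a few cm behind the beam), or estimated as a third free parameter.

## Fitting

Parameters are estimated by bounded trust-region non-linear least squares
(scipy `least_squares`) on the unweighted residuals observed − predicted
gate time. Bounds are MSS ∈ [2, 12] m/s, TAU ∈ [0.05, 3] s,
tc ∈ [−0.5, +1.0] s — wide enough never to bind on plausible human data; the
estimated correction is not constrained non-negative. Convergence tolerances
(1e−12 on step, cost and gradient; 500 function evaluations) sit far below
the 0.01 s resolution of gate data. Starting values: MSS₀ = 1.1× the last
segment's average speed, TAU₀ = first gate time minus the time that gate
would take at MSS₀ (clamped to [0.3, 1.5] s), tc₀ = 0.2 s. On
non-convergence the fit restarts once from MSS₀ × 1.2 before the result is
flagged `converged=False`; it never fails silently. Fitting uses no random
numbers, sorts gates internally (row order cannot matter), and requires more
gates than free parameters (≥ 3 for the two-parameter regimes, ≥ 4 for the
estimated regime). Input validation rejects non-monotone splits and implied
segment speeds at or above 13 m/s.

The `none` regime is exactly the `fixed` regime with correction 0, and the
estimated regime's objective can never exceed any fixed-regime member's —
both facts are asserted in the test suite.

## Force–velocity profile

Horizontal force is reconstructed along the modelled sprint as
`F_h(t) = m·a(t) + k·v(t)²`, inertial force plus aerodynamic drag. The drag
constant uses the conventional field-method chain: frontal area
`A = (0.2025·h^0.725·m^0.425)·0.266` m² from stature h and mass m, drag
coefficient Cd = 0.9, air density `ρ = 1.293·(P/760)·273/(273+T)` kg/m³
(defaults 760 mmHg, 20 °C → ρ ≈ 1.205). For a 62.3 kg, 1.674 m athlete this
gives k ≈ 0.246 N·s²/m².

The sprint is sampled on a uniform model-time grid, dt = 0.001 s (halving dt
moves every profile field by < 0.1 %; asserted), from 0 to the model time
needed to cover 35 m. F0 (N/kg) and V0 (m/s) are the intercepts of an
ordinary least-squares line through all (v, F_h/m) samples — with k = 0 the
relation is exactly linear and F0 = MAC, V0 = MSS. Pmax = F0·V0/4 is the
apex of the parabolic power–velocity relation and the FV slope is −F0/V0.
The ratio of force `RF = F_h/√(F_h² + (m·g)²)` (g = 9.81 m/s²) is evaluated
only from t = 0.3 s onward, excluding the initial push phase where the
resultant-force geometry differs; RFmax is RF at the 0.3 s boundary (RF is
monotone decreasing afterwards) and DRF is the slope of the linear RF–v fit
over the window, in % per m/s.

## Cohort comparison

Bias at a gate distance is the cohort mean of the residual observed −
predicted split time; its spread is the sample SD (undefined, reported as
missing, for n = 1). Effect sizes between regimes use paired-samples
Cohen's d with the pooled SD of the two vectors,
`d = (x̄ − ȳ)/√((s²ₓ + s²ᵧ)/2)`, labelled trivial (< 0.2), small (0.2–0.6),
moderate (0.61–1.20), large (1.21–2.0) and very large (2.1–4.0); boundary
ties go to the lower band. The pooled-SD variant (rather than the SD of
differences) is the one consistent with the magnitude labels conventionally
attached to these bands. Pearson correlations relate the estimated
correction to MAC and MSS across athletes. Inferential machinery
(repeated-measures ANOVA, post-hoc tests) is deliberately not implemented:
the package reports descriptive contrasts and effect sizes only.

## Synthetic cohorts

The generator draws per-athlete (MSS, TAU, tc, mass, stature) from
independent truncated normals with defaults matching a high-level female
soccer cohort: MSS 7.8 ± 0.45 m/s, TAU 1.10 ± 0.16 s, tc 0.25 ± 0.09 s
truncated to [0.05, 0.50] s, mass 62.3 ± 7.0 kg, stature 1.674 ± 0.064 m.
Gate times at 5/10/20/30/35 m are the model's gate-clock splits plus
independent Gaussian noise, SD 0.015 s — an engineering choice of the order
of infrared gate-system resolution, exposed in `CohortSpec`. Noise draws
that break the strict monotonicity a real gate system guarantees are redrawn
(up to 100 times). Truncation of the unbounded marginals uses wide physical
guard rails (e.g. MSS ∈ [4, 12] m/s) that essentially never clip under the
defaults. Parameters are independent by default; the observed negative
coupling between the estimated correction and acceleration in real cohorts
is an empirical finding, not an assumption, so a Gaussian-copula knob
(`tc_tau_correlation`) exists but defaults off.

What the twin does not emulate: within-athlete trial-to-trial variability,
velocity decay beyond ~6 s of sprinting, reaction-time structure in the lag,
or any coupling of anthropometrics with sprint parameters. Passing recovery
tests therefore shows the estimator is correct under the stated noise model,
not that real gate data satisfy that model.

## Problem sizes and numerical choices

Recovery and bias-structure checks use 200-athlete cohorts (standard errors
small enough to resolve a 1 % MSS bias); moment-convergence checks use 10⁴
parameter draws; the Lambert-W inversion is verified against brute-force
bisection (tolerance 1e−12) on 1000 random parameter/distance draws. The
reference-result script fits the published cohort-mean splits directly;
fit-of-means differs from the published mean-of-fits by a Jensen gap, which
is why those comparisons carry ~10 % bands.

## Known limitations

Mono-exponential only (no bi-exponential or velocity-decay variants); no
wind or bend adjustment; profile constants (Cd, frontal-area regression) are
population-level approximations; the estimated-correction regime needs at
least four gates and, with exactly four, leaves one residual degree of
freedom, so its RSE is noisy on minimal layouts.
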