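# Methods

## Scope

This package simulates a deterministic study of full-day light exposure:
(1) a two-week evening-reading crossover protocol (eBook at 30 lux vs
paper book at 3 lux, 18:00–22:00, under 90 or 500 lux daytime light),
run over ensembles of sleep and circadian phenotype parameters; and
(2) baseline-plus-bright-pulse schedules probing when during the day a
1 h, 5000 lux pulse shifts sleep timing versus boosting circadian
amplitude. All inputs are light schedules generated by
`circalux.protocols`; there is no external data and no randomness
anywhere in the pipeline.

## Circadian model

The pacemaker is the classical human circadian limit-cycle oscillator
("simpler model" van der Pol form) with a photoreceptor
activation/saturation front end (Process L). Constants, with units and
defaults:

| constant | value | meaning |
|---|---|---|
| α₀ | 0.05 min⁻¹ | photoreceptor activation scale |
| β | 0.0075 min⁻¹ | photoreceptor recovery rate |
| I₀ | 9500 lux | activation half-scale illuminance |
| G | 33.75 | photic drive gain |
| μ_v | 0.23 | van der Pol stiffness |
| k | 0.55 | light effect on angular frequency |
| 0.99669 | — | stiffness period-correction factor |
| p | 0.5, swept [0.5, 0.7] | photic sensitivity exponent |
| κ | 0.4, swept [0.4, 0.7] | PRC-shape coefficient in (1−κx)(1−κx_c) |
| τ_C | 24.2 h, swept [23.8, 24.4] | intrinsic period |

κ is identified with the state-modulation coefficient of the drive term:
it is the constant that shapes how identical light produces
phase-dependent responses, its reference value (0.4) is the lower
endpoint of the swept range, and no other fixed constant of the model
has that property. The dark free-run period reproduces τ_C to better
than 0.005 h (tested at 23.8/24.1/24.4). The numerically constructed PRC
to a 1 h 5000-lux pulse is biphasic — advances from CBTmin through the
subjective day, delays through the subjective evening, crossovers near
13.5 h after CBTmin and ~2 h before the next one — with no extended dead
zone (only isolated zero crossings).

CBTmin is the cyclic minimum of `x` (grid minima refined by three-point
quadratic interpolation, ties to the earliest time; successive minima
closer than 16 h — well below any cycle length in the swept τ_C range —
are collapsed to the deeper one, which suppresses spurious secondary
dips induced by bright pulses). DLMO = CBTmin − 7 h. Instantaneous
circadian amplitude is r(t) = √(x² + x_c²); "average amplitude" is its
trapezoid time-average over the last simulated day. The amplitude
definition lives in one function (`average_amplitude`) so it can be
swapped.

## Sleep model

A two-process homeostat with circadian-modulated thresholds:

- awake: dH/dt = (H_A − H)/τ_r with asymptote H_A = 23.5 and rise
  timescale τ_r = 18.2 h (the classical two-process wake-accumulation
  constant);
- asleep: dH/dt = −H/ꭓ (pure exponential decay; ꭓ is the swept
  "sleep-pressure decay" phenotype parameter);
- thresholds: upper = μ + c_a·x, lower = upper − Δ, with modulation
  amplitude c_a = 4.5. Both dip across the biological night (x is
  minimal at CBTmin), giving the standard two-process geometry: onset
  when rising pressure meets the falling upper threshold in the evening,
  wake when decaying pressure meets the rising lower threshold after
  CBTmin.

μ (mean upper-threshold level), Δ (threshold gap) and ꭓ are the swept
parameters; the reading of μ as the *mean level* of the modulated upper
threshold and ꭓ as the *sleep-phase* decay constant follows from their
names; the wake-phase rise is governed by its own fixed constants. The
non-swept constants (H_A, τ_r, c_a) are this package's calibration,
fixed once before any study quantity was computed, against a
physiological criterion taken from the protocol itself: the default
phenotype (μ=19, Δ=6, ꭓ=11), entrained to the 16:8 1000-lux schedule,
must show a normal-range sleep latency (5–25 min) after the 22:00
lights-off, wake between 5:30 and 6:00, and 7.3–8 h of sleep with
exactly two switches per day. The selected triple gives SOL 16.6 min,
wake 5:43, 7.44 h.

**Light gating.** In laboratory protocols, illuminance above 0.5 lux
both prevents sleep onset and terminates ongoing sleep (wake times were
prescribed; the 3 lux reading condition therefore also blocks sleep
until the 22:00 lights-off). In the pulse schedules the rule is disabled
(`wake_lux_threshold = inf`): their 50 lux nighttime floor would
otherwise forbid sleep entirely, and sleep there is intentionally
endogenous. During sleep the circadian model always receives 0 lux.

## Numerics

Fixed-step classical RK4 at dt = 0.01 h on a grid containing every
schedule breakpoint, so light discontinuities fall exactly on step
boundaries; the core is numba-compiled. Sleep/wake threshold crossings
are localized by bisection (re-integrating the partial step) to 1e-6 h;
light-gate transitions are resolved at grid points, where all step
changes of this study's schedules occur. Integration is deterministic —
identical inputs give bit-identical trajectories — and step-halving
moves the final CBTmin of a 10-day run by < 0.005 h. The integrator
aborts with a diagnostic (time and parameter set) on non-finite or
runaway states and enforces n ∈ [0, 1] at every step.

The canonical pre-equilibration state is the dark limit cycle near its
x-minimum (x = −1, x_c = 0), n = 0, H at the mean lower threshold,
awake; equilibration erases this choice (re-equilibrating an
equilibrated state moves CBTmin by < 1 min).

## Study conventions

- **Equilibration.** Every run starts from 30 days on the regular
  schedule (1000 lux from lights-on, 16 h light : 8 h dark). The
  pre-study lights-on time is a parameter (05:00–09:00 used by the
  initial-condition experiment; 06:00 otherwise). Lights-on later than
  08:00 wraps the lit period across midnight. The same convention is
  applied to the pulse runs, whose 20-day span otherwise carries a large
  entrainment transient into the last-day analysis.
- **Protocol layout.** Each condition occupies 5 reading days followed
  by 2 dim constant-posture (CP) assessment days (14 days total). CP
  illuminance is not specified by the source protocol; 3 lux (dim-light
  melatonin assessment convention) is the configurable default, applied
  across the whole CP wake period, with the habitual 22:00–06:00 dark
  sleep window retained.
- **Phase readouts** are the CBTmin clock times on days 7 and 13, and
  the eBook-attributable shift of a run is (CBTmin after the eBook week)
  − (CBTmin after the Book week), positive = delay, computed within a
  single two-condition run. Because day 7 follows two CP days while day
  13 follows five reading days (and subjects are still entraining into
  the protocol), a null protocol with identical reading conditions does
  not give exactly zero — the two order schedules then coincide, and the
  attributed shifts are exactly opposite instead, which is the invariant
  the tests assert.
- **SOL** is measured from each scheduled lights-off (lux dropping to
  ≤ 0.5, i.e. 22:00) to the model's sleep onset; nights without onset
  are missing, not zero. Ensemble SOL tables cover all five reading
  nights per condition (a `nights="45"` option restricts to nights 4–5).
- **Pulse schedules** follow the normative dialect: nighttime lux (50,
  or 0 in the full-darkness case) outside 06:00–22:00, linear ramps
  06:00–08:00 up and 20:00–22:00 down, a rectangular 1 h 5000-lux pulse
  placed relative to the scheduled 06:00 waking reference (identical
  forcing for every parameter set). The alternative dialect (ramp to
  zero 18:00–20:00) is available as `caption_ramps=True`. Pulses may not
  wrap past midnight; this is rejected rather than wrapped.
- **Validity filter.** A sleep-parameter set is retained iff every
  evaluated day of the equilibration run's steady state (the final 10
  days; lights-on-aligned 24 h windows) has ≥ 6.5 h sleep and exactly
  two switches. The ≥ reading follows the operative inclusion sentence
  of the study design. Events falling exactly on a window edge (the
  forced wake at lights-on) count toward the ending window.
- **Entrainment** of a CBTmin series: observed period = mean successive
  marker difference over the final 7 days, drift = period − 24 h,
  entrained iff |drift| < 0.02 h/day.

## Problem sizes

The ensembles are the study's own sizes (5×5×5 = 125 sets per grid, 30 d
equilibration + 14 d protocol per run, both orders, both baselines;
20-day pulse runs). The full acceptance pipeline is ~20,000 simulated
days and runs in about a minute; the test suite re-runs the ensembles at
full size.

## What the generator does and does not emulate

Schedules are idealized piecewise-linear photopic illuminance: constant
levels, sharp transitions, clean ramps. Real light exposure is sporadic,
spectrally diverse, and behaviorally gated; the model is driven by
photopic lux only (no melanopic irradiance, no separate rod/cone/ipRGC
pathways), has no melatonin dynamics (DLMO is a fixed 7 h offset from
the oscillator marker, so melatonin suppression is out of scope), and no
alerting effects of light. Passing tests therefore validate the coupled
oscillator–homeostat machinery and the protocol logic, not prediction of
field data from wearable light logs.

## Known limitations

- The non-swept sleep-side constants (H_A, τ_r, c_a) are a package
  calibration, not reference values; quantities that lean on the exact
  homeostat geometry across the whole grid — the ensemble SOL
  difference, the validity-filter count, pulse-night bedtimes — are
  sensitive to them. The ensemble *orderings* (brighter daytime →
  smaller SOL difference, smaller order effect, narrower phase-shift
  spread; drift at a 14 h pulse decreasing with baseline) are robust.
- With this parameterization a 1000-lux baseline is strong enough that
  the daily 14 h-after-waking pulse ends up phase-locked (residual drift
  +0.0005 h/day, still positive); at dimmer baselines the 14 h pulse
  leaves a clear >24 h drift. Conversely the 100-lux cells approach
  their locked phase slowly, so at day 20 the pulse-at-wake cell still
  carries ~0.04 h/day of convergence transient.
- Event localization assumes light-gate changes occur at schedule
  breakpoints (true for every schedule in this study); a ramp crossing
  the 0.5 lux gate inside a step would be resolved only at grid
  resolution.
- Sleep is monophasic by construction of the filter; napping and sleep
  architecture are out of scope.
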