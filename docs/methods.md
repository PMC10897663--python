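# Methods

This note documents the models, numerical choices and limitations behind
`archpwv`. Everything quantitative stated here is computed by the test
suite or `scripts/acceptance.py`; nothing is asserted that the code does
not reproduce.

## Mock-loop model

**Afterload.** The aorta-plus-periphery is a three-element Windkessel:
characteristic impedance `Zc = zc_fraction · R` (default 5%), peripheral
resistance `R` and compliance `C`. The storage pressure obeys
`Pc' = Q/C − Pc/(RC)`; because the drive is periodic, the steady-state
cycle is computed in closed form with an exponential integrator
(cumulative-trapezoid quadrature on a 4× oversampled grid, then decimated
to the acquisition grid), so no warm-up transient is simulated. Zone-3
pressure is `P = Pc + Zc·Q`.

**Drive.** Ventricular ejection is a half-sine occupying
`ejection_fraction` (default 0.35) of the cycle, scaled so the time-mean
flow equals the cardiac-output setting. The shape is the simplest one with
a well-defined foot; valves are not modeled. The cycle period is snapped
onto the sample grid (exact at the default 75 bpm / 1 kHz).

**Auto-tuning.** Mirroring the experimenters' manual knob-setting, `R` is
bisected until the mean pressure index `DBP + PP/3` reaches
`map_target_mmhg` and `C` until pulse pressure reaches `pp_target_mmhg`
(three alternating passes, ≤50 bisection steps each). Targets default to
MAP 94 / PP 44 mmHg rather than the window centers (95/45): centering both
would pin SBP exactly on its 125 mmHg window edge, whereas 94/44 implies
DBP 79.3 and SBP 123.3 mmHg, comfortably inside all four protocol windows
(DBP 75–85, SBP 115–125, PP 40–50, MAP 90–100). A run whose tuned baseline
misses any window raises a `TuningError` naming it.

**Wave speed.** The intrinsic wall wave speed is Moens–Korteweg
`c = sqrt(E·h/(2·ρ·r))` at the landing-zone radius `r = d2/2`, with water
as the circulatory fluid (`ρ = 1000 kg/m³`, overridable per specimen).
Arch angulation is *not* given a mechanistic model; the hypothesis that a
steeper arch raises systemic resistance and thereby pressure and wave
speed is exposed as two parameters: Type III multiplies the tuned `R` by
`arch_resistance_factor` (default 1.085) without re-tuning, and the
configuration wave speed is `c · (MAP/MAP_baseline)^arch_stiffening_exponent`
(default exponent 1). These defaults are calibrated to raise MAP by
~8 mmHg and wave speed by ~8.5% in Type III, the directionality and
magnitude the bench study reported; they live in the config, not in code.
Type III also lengthens the centerline by `arch_length_delta_cm`
(default 0.7 cm, the observed mean difference between configurations).

**Stent-graft.** Deployment stiffens only the covered 112 mm: local wave
speed there is `κ·c` (default `κ = 1.28`, calibrated to a ~7% whole-aorta
PWV rise at the cohort-mean geometry, since
`PWV_after/PWV_before = L / ((L − L_s) + L_s/κ)`). Pressures are left
unchanged by the stent — the small post-TEVAR pressure shifts seen on the
bench are not modeled.

**Waveforms and noise.** The distal flow record is the analytic proximal
waveform evaluated at `t − TT` (periodic), so fractional-sample delays are
exact, damped by `distal_damping` (default 0.85). Measurement noise is
additive Gaussian with SD `noise_sd` × peak-to-peak amplitude per record;
the default 0.005 corresponds to ~0.2 mmHg on a 45 mmHg pulse, the order
of a bench pressure sensor's noise floor. Noise streams are deterministic
substreams of the config seed (one per record), and all study-level seeds
derive from a single master seed.

## Measurement pipeline

Records are cut into complete cycles (`round(fs·60/HR)` samples each,
partial tail discarded; default minimum 25 cycles), ensemble-averaged and
mean-subtracted. The transit time is the argmax over circular lags in
`(0, cycle/2]` of the normalized circular cross-correlation, refined by
three-point parabolic interpolation; ties take the smallest lag, and a
peak below `correlation_floor` (default 0.5) raises an error. Identical
inputs return TT = 0 with a degenerate flag rather than an error (useful
in null tests). On smooth pulses the refinement is accurate to well under
0.1 sample at 1 kHz — needed, since a 100 ms transit time read at integer
lags alone would quantize PWV at the 1% level, coarser than the 0.01 m/s
reporting precision.

Centerline length is the polyline (piecewise-linear) arc length of the
ordered annotation points, scaled by `2.5 cm / pixel-length(reference bar)`;
point order is taken as given and no spline is fitted — the manual protocol
defines only ordered points, and the polyline's discretization error is
bounded and testable (it always underestimates a smooth curve; a
101-point semicircle of radius 10 cm is short of `π·10` by <0.01 cm).
Lengths at the three continuous-flow pressures (80/100/120 mmHg) are fitted
by ordinary least squares against pressure, and the length at the MAP of
the pulsatile acquisition enters the PWV quotient. DBP/SBP are means of
per-cycle extremes; PP = SBP − DBP and MAP = DBP + PP/3 are identities
enforced by the `PressureSummary` type.

## Statistics

Paired contrasts route on a Shapiro–Wilk test of the differences at
α = 0.05 (two-sided throughout, no multiplicity correction): normal-looking
differences go to the paired t test, otherwise Wilcoxon signed-rank with
zeros dropped, exact null for ≤25 tie-free non-zero differences and a
continuity-corrected normal approximation above. Identical vectors yield a
degenerate result with p = 1; constant non-zero differences are an error.
Note that Shapiro–Wilk is severe on tiny samples with ties — differences
like (1, 1, 2) at n = 3 are routed to Wilcoxon even though a hand paired-t
is computable; an explicit `test=` override exists for such cases.

ICC(A,1) (two-way model, single rater, absolute agreement) is computed
from the two-way ANOVA mean squares,
`ICC = (MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE))`, with an F-based
confidence interval using Satterthwaite denominator degrees of freedom;
scipy supplies only the F quantiles. A constant matrix is degenerate
(0/0) and raises. The sample-size routine returns the smallest n whose
two-sided noncentral-t power (df = n−1, noncentrality `d_z·√n`) reaches
the target; an effect size near `d_z = 1.3` reproduces the protocol's
n = 10 at α = .05, power = .95.

## Study orchestration

Pairing is within-specimen: each sample is acquired in both arch
configurations with identical specimen parameters and cardiac output (the
bench re-mounts the same aorta and readjusts flow to match), and the
stent-eligible subgroup (landing-zone diameter inside the unrounded
10–20% window of the 26 mm graft) is re-acquired stented in both
configurations. Specimens whose tuning or pipeline fails are excluded
listwise with a recorded reason. Percent changes are reported under both
estimands — mean of per-specimen ratios and ratio of configuration means —
because they answer different questions and differ numerically.

The cohort generator draws diameters as independent truncated normals
(±3 SD) with the tapering order enforced by rejection, lengths and length
slopes likewise, and back-solves each specimen's wall modulus from a
target wave-speed distribution (mean 3.53, SD 0.40 m/s) via
Moens–Korteweg. Per-specimen cardiac output is a truncated normal inside
the 4.5–5.5 L/min protocol window.

## What the generator does and does not emulate

It emulates: the paired design, the pressure windows and their manual
attainment, ≥25-cycle acquisitions, fractional-sample transit delays,
waveform and annotation noise, diameter-based stent eligibility, and the
calibrated directional effects of arch angulation and stenting. It does
not emulate: wave reflections or waveform shape change along the aorta
(the distal waveform is a damped delayed copy), between-specimen
variability in the arch response (the resistance factor is a single
scalar, so per-specimen percent changes are nearly uniform and their
spread is far smaller than a real cohort's), stent-induced pressure
changes, non-stationary cycles, or any image-processing step. Passing
tests therefore validate the measurement chain and the statistical layer,
not the biology of real aortas.

## Problem sizes and tolerances

Monte-Carlo checks use sizes chosen to make their tolerances sharp on one
CPU: 200 random fractional delays for the transit-time oracle (error ≤0.2
samples noise-free, ≤1 sample at 20 dB SNR), 10⁴ null replicates for the
paired-test type-I error (band 0.04–0.06), 40 replicates per wave speed on
the 2.5–5.5 m/s grid for PWV recovery (|bias| < 1%, SD < 3%), 100 tuned
runs for pressure-window attainment, and 20 replicate n = 24 cohorts for
the calibrated-structure checks. The ICC implementation is compared to a
brute-force sum-of-squares oracle to 1e-10 and to pingouin as an
independent package.

## Known limitations

- The arch-angulation mechanism is a parameterized hypothesis; the
  simulator can reproduce the observed directionality under any
  monotone mechanism that raises MAP and wave speed together.
- The eligible fraction of a normal cohort with the observed diameter
  spread (~45–50%) is lower than the 62.5% a real, more clustered cohort
  showed; the generator does not model that clustering.
- PWV percent-change SDs are noise-dominated and much smaller than real
  between-specimen spreads, so significance levels of calibrated contrasts
  are optimistic relative to the bench.
- The Windkessel is lumped: no spatial wave propagation is simulated; the
  transit time is imposed from the wave-speed model rather than emerging
  from distributed mechanics.
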