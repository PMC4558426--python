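# Methods

This note documents the models, estimators, defaults and numerical choices
behind `thermocode`, and what the synthetic validation does and does not
demonstrate.

## Stimulus conditioning

A recording's stimulus is a thermocouple trace sampled nominally at 4 Hz
with ~0.01 °C accuracy. Conditioning proceeds in three steps:

1. **Gaussian smoothing** (`stimulus.gauss_smooth`), kernel SD 0.5 s by
   default, truncated at ±4σ, edge-renormalized so constants are preserved
   and the output never leaves the input range. The kernel width is a
   convention (the recording practice it mirrors names no width); 0.5 s
   suppresses single-sample sensor noise without blurring ramps whose
   features live on the seconds scale. Affine segments pass through
   unchanged in the interior, so ramp rates are unbiased.
2. **1-s binning** (`stimulus.bin_stimulus`): half-open windows [t, t+1)
   anchored at the trace start and re-anchored at stimulus onset for
   response analysis (so the baseline and response windows fall on exact
   bin edges). Each bin carries its mean temperature and its *changing
   rate*, the within-bin least-squares slope of temperature on time —
   exact on noiseless ramps, and more noise-robust at 4 samples/bin than
   first differences of bin means. Bins with fewer than 2 samples are
   dropped.
3. **Onset detection** (`stimulus.detect_onset`): the first bin whose
   |rate| reaches a floor (default 0.02 °C/s) and which starts a run of 3
   such bins; the run requirement suppresses single-bin noise triggers.
   A protocol-supplied onset, when available, overrides detection.

## Spike-train measures

Activity is quantified two ways, matching how the two neuron types are
analyzed:

- **Instantaneous frequency (IF)** — reciprocal inter-spike interval,
  assigned to the bin containing the *second* spike of the pair (the
  instant the measurement exists; the assignment is a documented
  convention). The per-bin **median IF** is robust to single long or short
  intervals. Bins with no IF sample are *missing*, not zero: a zero would
  bias suppression fits.
- **Mean rate** — spike count per 1-s bin, which has complete coverage
  (a silent bin is a true 0 APs/s) and is used for the ST analysis.

**nIF normalization**: the mean median-IF over the 10 s before onset is
the baseline; every bin's nIF is 100·(median IF)/baseline, so the baseline
window averages 100% by construction. The **noise level** is twice the SD
of the baseline-window nIF. At least 5 of the 10 baseline bins must carry
spikes, otherwise the recording is rejected as unanalyzable.

## TT (flux-detector) dose–response

Response bins are taken from the 240 s after onset: bins driven in the
requested direction whose measured |rate| exceeds a floor (default = the
onset floor; this excludes plateau bins whose tiny measured rates are pure
sensor noise and whose ln would otherwise dominate the regression as
high-leverage points), and whose nIF clears the resting noise band
(above 100 + noise for cooling, below 100 − noise for heating). Heating
fits use sustained-suppression bins; fully silenced bins carry no IF
sample and therefore never enter.

The regression of nIF on ln|r| (ordinary least squares; two-sided t-test
on the slope) is accepted when p < 0.05 and the Pearson correlation is
moderate in the direction-appropriate sense (r > 0.3 cooling,
r < −0.3 heating). The residual SD uses the n−1 divisor. Units stimulated
at several ramp rates are characterized by one pooled regression over all
their recordings' points, each recording normalized to its own baseline
(`pipeline.analyze_tt_unit`); the noise level used for the threshold is
the mean across those baselines.

**Log-base convention.** The regression is computed in natural log, so the
resolving power Δx = (2σ/|b|)·Φ⁻¹(γ) is a dimensionless stimulus fraction
and the just-noticeable difference at drive r is simply Δx·|r| (first
order). Differential sensitivity alone is *reported* per decade
(slope·ln 10). This is the only convention under which per-decade
sensitivities and the Δx→JND conversions (0.372 at −0.1 °C/s → 0.037 °C/s)
are mutually consistent. `phi_rounding="paper"` uses the tabulated
Φ⁻¹(0.9) = 1.28 instead of 1.2816 to match hand-computed values.

**Discrimination convention behind Δx.** The closed form corresponds to a
midpoint criterion: two operating points are resolvable when an
observation (noise SD σ) falls on its own side of the midpoint between the
two regression means with probability γ, i.e. when the mean separation
|b|·Δx reaches 2σ·Φ⁻¹(γ). The test suite checks the closed form against a
Monte-Carlo bisection oracle built on exactly this rule (agreement within
10% at σ/|b| ∈ {0.05, 0.15, 0.3}).

**Detection threshold** is the continuous crossing of the fitted line with
the noise band, solved in closed form, signed by direction; if the
crossing lies below the smallest intensity actually observed, the estimate
is clipped there and flagged (the line was never tested below that point).
The discrete alternative (smallest supra-noise tested intensity) exists
behind the same flag machinery for sensitivity analysis.

## ST (steady-temperature) sigmoid

The mean rate is fitted with a decreasing four-parameter logistic by
Gauss–Newton with step halving (normal equations solved by least squares;
analytic Jacobian; convergence at gradient ∞-norm < 10⁻⁸·max(1, SSE) or
200 iterations, returning a `converged` flag rather than raising so a
stubborn unit cannot abort a cohort run). Initialization is data-driven:
plateau levels from the extreme 10% of the temperature range, turning
point from the mid-span crossing of a lightly smoothed rate, width from
the quarter-span crossings. The functional form is a modeling choice — the
original procedure names only "sigmoidal" — and the logistic's slope at
the turning point has the closed form −(r_high − r_low)/(4w).

**Working range, 10% rule.** Two readings are implemented and reported:
`literal` (default) bounds the range at activities 0.90·r_high and
1.10·r_low; `span` bounds it 10% of the plateau span inside each plateau.
The literal rule tracks the original wording but degenerates as
r_low → 0 (1.10·0 is never attained), where the span rule remains defined
and is symmetric about T0 (working range T0 ± w·ln 9). Boundary activities
are inverted through the fitted logistic,
T(a) = T0 + w·ln((r_high − a)/(a − r_low)), and the curve evaluated at the
returned temperatures reproduces the boundary activities to 10⁻⁶.

**Resolving power in °C** comes from an OLS of mean rate on temperature
over the bins within ±1 °C of T0 (where the logistic is nearly linear and
sensitivity maximal), with the same 2σ/|b|·Φ⁻¹(γ) statistic. **Plateau
comparison** uses per-recording mean rates below/above the working range,
a paired Wilcoxon signed-rank test when recordings are paired, a rank-sum
test otherwise.

## Synthetic data generator

The generator emulates the bench protocol — hold at 25 °C, ramp at a
constant signed rate (|r| in 0.01–0.43 °C/s), 500-s plateau, ramp back —
sampled at 4 Hz with i.i.d. Gaussian sensor noise (SD 0.01 °C, the stated
accuracy; no drift term).

Firing is phenomenological (no membrane or channel biophysics):

- **TT model**: resting 40 Hz; cooling past a rate threshold θ = 0.02 °C/s
  drives nIF to 100 + g_cool·ln(|r|/θ) (default gain 60 %/decade); heating
  suppresses symmetrically with a floor at nIF 0, optionally at a
  sustained 20% to mimic units whose heating response plateaus instead of
  silencing; away from drive, nIF relaxes exponentially to 100% with
  τ = 30 s (adaptation is observed but its kinetics are unreported, so τ
  is a free, documented parameter); silent outside the 21–38 °C working
  range. The drive is computed from the same smoothed, binned rate the
  analysis measures.
- **ST model**: the decreasing logistic with plateaus 50/29.5 APs/s,
  turning point 30 °C, width 0.7885 °C (peak sensitivity −6.5 APs/°C).

Spikes come from an inhomogeneous gamma-renewal process via time
rescaling: unit-mean Gamma(k, 1/k) intervals in operational time
Λ(t) = ∫rate dt, mapped back through the piecewise-linear inverse of Λ.
Renewal order k = 4 by default — the resting discharge of both neuron
types is visibly more regular than Poisson — and k = 1 recovers an
inhomogeneous Poisson process. Expected spike count equals the integrated
rate. All randomness flows through explicit integer seeds; identical
(model, protocol, seed) triples are byte-identical.

**What the generator does not emulate:** slow physiological drift of
excitability, bursting, spike-sorting contamination, rate-dependent ISI
regularity, or any coupling between temperature and spike amplitude.
Passing recovery tests therefore demonstrate the correctness of the
estimators under the stated response model, not robustness to every
artifact of real recordings.

## Validation scale and a known bias

Recovery checks run at desk scale: 20 TT units × 3 cooling ramps
(−0.03/−0.1/−0.3 °C/s, 3 °C deep, 500-s plateaus) and 7 ST units
(+0.01 °C/s ramp over 23→37 °C). ST recovery is sharp: all units converge
with turning-point errors < 0.05 °C and sensitivity errors < 5%.

TT recovery exposes a genuine property of the published procedure. With a
40 Hz resting discharge at renewal order 4, the per-bin median-IF has a
relative SD near 10%, so the resting noise band is ~20% wide — wider than
the true response (+10.6%) at the −0.03 °C/s ramp. The supra-noise
selection rule then admits only the upper noise tail at that intensity,
which biases the low-intensity end of the pooled regression upward and
attenuates the fitted sensitivity (median ≈ 38 %/decade for a 60 %/decade
generator), while the fitted-line/noise-band crossing correspondingly
underestimates the noise-determined detection threshold. Dropping the
sub-threshold intensity restores the slope, confirming selection
truncation as the cause. The bias is inherent to regressing only
supra-noise bins near threshold; the package implements the procedure as
published and surfaces the bias through its synthetic cohort rather than
silently "correcting" it.

## Degenerate inputs and tie-breaks

- Traces must be strictly increasing in time; duplicate spike times are
  rejected with the offending index.
- Smoothing with a kernel narrower than 10⁻³ samples is the identity.
- Duplicate ln|r| values are allowed in the regression; no aggregation is
  performed before fitting.
- A constant parameter vector makes a cohort Pearson correlation
  not-computable; it is reported as NaN with a note, never as 1.
- Cohort correlations and group comparisons are exploratory and reported
  unadjusted, with a Holm-adjusted column alongside for transparency.
- A failing unit never aborts a cohort run; its error is recorded with
  unit id and stage name.
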