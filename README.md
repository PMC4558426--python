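# thermocode

Quantitative characterization of the two cold-sensitive neurons of insect
antennal peg-in-pit sensilla, from temperature traces and sorted spike
times. The package implements the complete analysis pipeline for both
response types, plus a synthetic-data generator with known ground truth so
that every stage can be validated by parameter recovery — no recordings
required.

**Who it is for:** sensory neurophysiologists analyzing thermoreceptor
dose–response data (a 4 Hz thermocouple trace plus spike-sorted unit
times per recording), and anyone needing a tested reference implementation
of the resolving-power statistic for rate-coded sensory neurons.

## The two analyses

**Transient-temperature (TT) neuron — a thermal flux detector.** Its
phasic discharge encodes the temperature changing rate r (°C/s). Activity
is measured as the per-1-s-bin median instantaneous frequency, normalized
to the 10-s pre-stimulus baseline (nIF, %; baseline ≡ 100%). Following the
Weber–Fechner law, response bins above the resting noise band
(100 ± 2·SD) are regressed on ln|r|:

    nIF = a + b·ln|r|

which yields three readouts:

- *detection threshold* — the |r| where the fitted line crosses the noise
  band (the smallest change eliciting a supra-noise response);
- *differential sensitivity* — the slope, reported per decade of stimulus
  intensity (b·ln 10, in %/decade);
- *resolving power* — Δx = (2σ/|b|)·Φ⁻¹(γ), with σ the residual SD about
  the regression (divisor n−1), Φ⁻¹ the standard-normal quantile and
  γ = 0.9 the required detection probability (Φ⁻¹(0.9) = 1.28). Because
  the regression is in natural log, Δx is a dimensionless fraction of the
  stimulus: a unit driven at r resolves a change of Δx·|r| °C/s (the
  just-noticeable difference, `jnd`).

**Steady-temperature (ST) neuron — an absolute-temperature detector.**
Its mean rate in 1-s windows sits on two plateaus joined by a sigmoid of
temperature, fitted by Gauss–Newton least squares:

    rate(T) = r_low + (r_high − r_low) / (1 + exp((T − T0)/w))

The slope at the turning point, −(r_high − r_low)/(4w) in APs/°C, is the
neuron's peak sensitivity; the working range is bounded by the 10%
departure rule from the two plateaus; and the resolving power in °C uses
the same 2σ/|b|·Φ⁻¹(γ) statistic on a linear regression within ±1 °C of
T0.

See `docs/methods.md` for assumptions, parameter defaults, numerical
details and known limitations.

## Worked example

Simulate one unit of each type and analyze it:

```python
import thermocode as tc
from thermocode.synthetic import (STNeuronModel, TTNeuronModel,
                                  simulate_st_recording, simulate_tt_recordings)

proto, trace, train = simulate_st_recording(STNeuronModel(), seed=1)
rec = tc.Recording("st_demo", "ST", trace, train, protocol_onset=proto.onset)
fit = tc.run_recording(rec).st

sims = simulate_tt_recordings(TTNeuronModel(), seed=1)
recs = [tc.Recording(f"tt_demo_r{j}", "TT", tr, sp, protocol_onset=p.onset)
        for j, (p, tr, sp) in enumerate(sims)]
ttfit, base = tc.analyze_tt_unit(recs)
```

prints (via the obvious f-strings):

```
turning point T0     = 29.99 degC
peak sensitivity     = -6.30 APs/degC
activity plateaus    = 50.3 / 29.4 APs/s
working range        = 29.04 - 31.49 degC
resolving power      = 1.34 degC

resting activity     = 42.6 Hz, noise level 26.7%
diff. sensitivity    = 38.4 %/decade (r=0.72, p=3.3e-10)
detection threshold  = -0.026 degC/s
```

The ST unit was generated with plateaus 50/29.5 APs/s, turning point
30 °C and peak sensitivity −6.5 APs/°C: the fit recovers all of them
closely. The TT unit was generated with a 60 %/decade cooling gain; the
recovered sensitivity is attenuated because the supra-noise selection rule
truncates the response distribution at near-threshold intensities — a
property of the published procedure that the synthetic cohort makes
visible (discussed in `docs/methods.md`).

The same pipeline runs from the shell:

```
thermocode simulate --out data/ --seed 1 --n-tt 3 --n-st 2
thermocode analyze  --data data/ --out results/
thermocode summarize --results results/ --out summary.csv
thermocode reproduce-worked-examples
```

`analyze` writes per-unit JSON results, a cohort CSV, summary tables,
exploratory correlations and a run manifest; reruns with the same inputs
and configuration are byte-identical.

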