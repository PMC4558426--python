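"""Synthetic stimulation protocols and spike trains with known ground truth.

Recordings of the two antennal cold-receptor types are emulated so that the
analysis stages can be validated by parameter recovery. The stimulation
protocol mirrors the bench procedure: hold at a starting temperature
(nominally 25 degC), ramp at a constant rate (|r| between 0.01 and
0.43 degC/s), hold a 500-s plateau, and ramp back at the opposite rate. The
thermocouple is emulated by sampling the waveform at 4 Hz and adding i.i.d.
Gaussian noise (default SD 0.01 degC, the sensor accuracy).

Firing is a phenomenological rate model driven through an inhomogeneous
gamma-renewal spike generator (time rescaling); no biophysics is modeled.
The TT (flux detector) model fires at its resting rate at steady
temperature, responds to cooling beyond a rate threshold theta with
nIF = 100 + gain_cool * ln(|r|/theta) (suppression symmetric for heating),
relaxes exponentially back to baseline at the plateau, and falls silent
outside its working temperature range. The ST model's rate is a decreasing
logistic of temperature between two plateaus. Renewal order 4 by default:
the resting discharge of both neuron types is visibly more regular than
Poisson.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .spiketrain import SpikeTrain
from .stimulus import TemperatureTrace, bin_stimulus, gauss_smooth

__all__ = [
    "StimulusProtocol",
    "TTNeuronModel",
    "STNeuronModel",
    "RateProfile",
    "build_protocol",
    "generate_temperature_trace",
    "tt_rate_profile",
    "st_rate_profile",
    "simulate_spikes",
    "write_recording",
]

LN10 = math.log(10.0)


@dataclass(frozen=True)
class StimulusProtocol:
    """Trapezoidal temperature protocol: hold, ramp, plateau, ramp back, hold."""

    start_temp: float  # degC
    plateau_temp: float  # degC
    ramp_rate: float  # degC/s, signed; the return ramp uses -ramp_rate
    plateau_hold: float  # s
    pre_hold: float = 60.0  # s at start_temp before the ramp
    post_hold: float = 30.0  # s at start_temp after the return ramp
    sample_rate: float = 4.0  # Hz

    def __post_init__(self) -> None:
        if abs(self.ramp_rate) < 1e-3:
            raise ValueError("|ramp_rate| must be >= 0.001 degC/s")
        if self.plateau_hold < 0 or self.pre_hold < 0 or self.post_hold < 0:
            raise ValueError("hold durations must be >= 0")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        delta = self.plateau_temp - self.start_temp
        if delta == 0 or math.copysign(1.0, delta) != math.copysign(1.0, self.ramp_rate):
            raise ValueError(
                "ramp_rate sign must match the plateau_temp - start_temp direction"
            )

    @property
    def ramp_duration(self) -> float:
        return abs(self.plateau_temp - self.start_temp) / abs(self.ramp_rate)

    @property
    def onset(self) -> float:
        """Time of stimulus onset (start of the first ramp)."""
        return self.pre_hold

    @property
    def total_duration(self) -> float:
        return self.pre_hold + 2 * self.ramp_duration + self.plateau_hold + self.post_hold

    def knots(self) -> tuple[np.ndarray, np.ndarray]:
        """Breakpoint (time, temperature) pairs of the piecewise-linear waveform."""
        d = self.ramp_duration
        t = np.array(
            [
                0.0,
                self.pre_hold,
                self.pre_hold + d,
                self.pre_hold + d + self.plateau_hold,
                self.pre_hold + 2 * d + self.plateau_hold,
                self.total_duration,
            ]
        )
        y = np.array(
            [
                self.start_temp,
                self.start_temp,
                self.plateau_temp,
                self.plateau_temp,
                self.start_temp,
                self.start_temp,
            ]
        )
        return t, y

    def waveform(self, times: np.ndarray) -> np.ndarray:
        kt, ky = self.knots()
        return np.interp(times, kt, ky)


def build_protocol(
    ramp_rate: float,
    plateau_temp: float,
    plateau_hold: float,
    start_temp: float = 25.0,
    sample_rate: float = 4.0,
    pre_hold: float = 60.0,
    post_hold: float = 30.0,
) -> StimulusProtocol:
    """Construct a stimulation protocol, validating the ramp direction.

    The waveform ramps from ``start_temp`` to ``plateau_temp`` at
    ``ramp_rate``, holds ``plateau_hold`` seconds, then ramps back at the
    same rate with opposite sign. Raises on a zero ramp rate or a sign
    mismatch between the ramp and the temperature difference.
    """
    return StimulusProtocol(
        start_temp=start_temp,
        plateau_temp=plateau_temp,
        ramp_rate=ramp_rate,
        plateau_hold=plateau_hold,
        pre_hold=pre_hold,
        post_hold=post_hold,
        sample_rate=sample_rate,
    )


def generate_temperature_trace(
    protocol: StimulusProtocol,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> TemperatureTrace:
    """Sample the protocol waveform at its sample rate with Gaussian sensor noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    n = int(round(protocol.total_duration * protocol.sample_rate)) + 1
    times = np.arange(n) / protocol.sample_rate
    temps = protocol.waveform(times)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        temps = temps + rng.normal(0.0, noise_sd, size=n)
    return TemperatureTrace(times, temps)


@dataclass(frozen=True)
class TTNeuronModel:
    """Phenomenological flux-detector model.

    Gains are in nIF percent per ln-unit of stimulus rate; divide a
    per-decade gain by ln 10 (e.g. 60 %/decade -> 26.06 %/ln-unit).
    ``heat_floor_nif`` > 0 emulates units whose heating response settles at
    a sustained ~20% level instead of complete silence.
    """

    resting_rate: float = 40.0  # Hz
    gain_cool: float = 60.0 / LN10  # nIF % per ln-unit of cooling rate
    gain_heat: float = 32.33 / LN10  # nIF % per ln-unit of heating rate
    threshold_rate: float = 0.02  # degC/s, response onset theta
    adapt_tau: float = 30.0  # s, exponential return to baseline
    working_temp_low: float = 21.0  # degC; silent below
    working_temp_high: float = 38.0  # degC; silent above
    isi_shape: float = 4.0  # gamma renewal order
    heat_floor_nif: float = 0.0  # % sustained floor under heating

    def __post_init__(self) -> None:
        if self.resting_rate <= 0:
            raise ValueError("resting_rate must be positive")
        if self.threshold_rate <= 0:
            raise ValueError("threshold_rate must be positive")
        if self.adapt_tau <= 0:
            raise ValueError("adapt_tau must be positive")
        if self.working_temp_low >= self.working_temp_high:
            raise ValueError("working_temp_low must be < working_temp_high")
        if self.isi_shape < 1:
            raise ValueError("isi_shape must be >= 1")
        if not 0 <= self.heat_floor_nif < 100:
            raise ValueError("heat_floor_nif must lie in [0, 100)")

    def driven_nif(self, rate: float) -> float | None:
        """Driven nIF target for a changing rate, or None below threshold."""
        theta = self.threshold_rate
        if rate < -theta:
            return 100.0 + self.gain_cool * math.log(-rate / theta)
        if rate > theta:
            return max(self.heat_floor_nif, 100.0 - self.gain_heat * math.log(rate / theta))
        return None


@dataclass(frozen=True)
class STNeuronModel:
    """Steady-temperature detector: decreasing logistic rate vs temperature."""

    rate_high: float = 50.0  # APs/s, low-temperature plateau
    rate_low: float = 29.5  # APs/s, high-temperature plateau
    midpoint_temp: float = 30.0  # degC, turning point
    width: float = 0.7885  # degC (slope at T0 = -(high-low)/(4 w) ~ -6.5 APs/degC)
    isi_shape: float = 4.0

    def __post_init__(self) -> None:
        if not self.rate_high > self.rate_low >= 0:
            raise ValueError("need rate_high > rate_low >= 0")
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.isi_shape < 1:
            raise ValueError("isi_shape must be >= 1")

    def rate_at(self, temp):
        """Model firing rate at a temperature (vectorized)."""
        u = (np.asarray(temp, dtype=float) - self.midpoint_temp) / self.width
        out = self.rate_low + (self.rate_high - self.rate_low) / (1.0 + np.exp(u))
        return float(out) if np.isscalar(temp) else out


@dataclass(frozen=True)
class RateProfile:
    """Per-bin target firing rate driving the spike generator."""

    bin_starts: np.ndarray  # s
    rates: np.ndarray  # Hz
    nif: np.ndarray | None = None  # % (TT only)
    bin_width: float = 1.0

    @property
    def expected_count(self) -> float:
        return float(np.sum(self.rates) * self.bin_width)


def tt_rate_profile(
    model: TTNeuronModel,
    trace: TemperatureTrace,
    bin_width: float = 1.0,
    smooth_sigma: float = 0.5,
) -> RateProfile:
    """Target rate of a TT unit along a temperature trace.

    Per 1-s bin with smoothed changing rate r: cooling beyond theta drives
    nIF to 100 + gain_cool*ln(|r|/theta); heating beyond theta suppresses to
    max(floor, 100 - gain_heat*ln(r/theta)); otherwise nIF relaxes toward
    100 from its last driven value with time constant adapt_tau. The firing
    rate is resting_rate * nIF/100, forced to 0 outside the working
    temperature range, and never negative.
    """
    if trace.duration < 20.0:
        raise ValueError("trace must span at least 20 s")
    bins = bin_stimulus(gauss_smooth(trace, smooth_sigma), bin_width)
    starts = np.array([b.bin_start for b in bins])
    nif = np.empty(len(bins))
    decay = math.exp(-bin_width / model.adapt_tau)
    state = 100.0
    for i, b in enumerate(bins):
        driven = model.driven_nif(b.changing_rate)
        state = driven if driven is not None else 100.0 + (state - 100.0) * decay
        nif[i] = state
    rates = model.resting_rate * nif / 100.0
    temps = np.array([b.mean_temp for b in bins])
    outside = (temps < model.working_temp_low) | (temps > model.working_temp_high)
    rates[outside] = 0.0
    np.maximum(rates, 0.0, out=rates)
    return RateProfile(bin_starts=starts, rates=rates, nif=nif, bin_width=bin_width)


def st_rate_profile(
    model: STNeuronModel,
    trace: TemperatureTrace,
    bin_width: float = 1.0,
    smooth_sigma: float = 0.5,
) -> RateProfile:
    """Target rate of an ST unit: the logistic evaluated at per-bin mean temperature."""
    bins = bin_stimulus(gauss_smooth(trace, smooth_sigma), bin_width)
    starts = np.array([b.bin_start for b in bins])
    temps = np.array([b.mean_temp for b in bins])
    return RateProfile(
        bin_starts=starts, rates=model.rate_at(temps), bin_width=bin_width
    )


def simulate_spikes(
    profile: RateProfile,
    isi_shape: float = 4.0,
    seed: int = 0,
) -> SpikeTrain:
    """Inhomogeneous gamma-renewal spike train by time rescaling.

    In operational time Lambda(t) = integral of the rate, inter-spike
    intervals are i.i.d. Gamma(isi_shape, scale=1/isi_shape) — unit mean, so
    the expected spike count equals the integrated rate; ``isi_shape = 1``
    reduces to an inhomogeneous Poisson process. Rescaled spike times are
    mapped back through the piecewise-linear inverse of Lambda.
    """
    if isi_shape < 1:
        raise ValueError("isi_shape must be >= 1")
    rates = np.asarray(profile.rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be >= 0")
    w = profile.bin_width
    lam_cum = np.concatenate([[0.0], np.cumsum(rates * w)])
    edges = np.concatenate(
        [profile.bin_starts, [profile.bin_starts[-1] + w]]
    )
    total = lam_cum[-1]
    if total == 0:
        return SpikeTrain(np.empty(0))
    rng = np.random.default_rng(seed)
    # draw unit-mean gamma ISIs in operational time until the budget is spent
    chunks: list[np.ndarray] = []
    consumed = 0.0
    margin = int(total + 6.0 * math.sqrt(total / isi_shape) + 20)
    while consumed < total:
        isis = rng.gamma(shape=isi_shape, scale=1.0 / isi_shape, size=margin)
        chunks.append(isis)
        consumed += float(isis.sum())
        margin = max(64, margin // 4)
    s = np.cumsum(np.concatenate(chunks))
    s = s[s < total]
    times = np.interp(s, lam_cum, edges)
    return SpikeTrain(times)


def write_recording(
    out_dir: str | Path,
    unit_id: str,
    trace: TemperatureTrace,
    train: SpikeTrain,
    ground_truth: dict,
) -> dict[str, Path]:
    """Write one simulated unit: temperature CSV, spikes CSV, truth sidecar.

    Files are ``<unit_id>_temperature.csv`` (time_s, temp_c),
    ``<unit_id>_spikes.csv`` (spike_time_s) and ``<unit_id>_truth.json``
    carrying the generator's model parameters and protocol.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "temperature": out_dir / f"{unit_id}_temperature.csv",
        "spikes": out_dir / f"{unit_id}_spikes.csv",
        "truth": out_dir / f"{unit_id}_truth.json",
    }
    pd.DataFrame({"time_s": trace.times, "temp_c": trace.temps}).to_csv(
        paths["temperature"], index=False
    )
    pd.DataFrame({"spike_time_s": train.spike_times}).to_csv(
        paths["spikes"], index=False
    )
    with open(paths["truth"], "w") as fh:
        json.dump(ground_truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def _as_truth(obj) -> dict:
    d = asdict(obj)
    return {k: (float(v) if isinstance(v, (int, float)) else v) for k, v in d.items()}


def simulate_tt_recordings(
    model: TTNeuronModel,
    ramp_rates: tuple[float, ...] = (-0.03, -0.1, -0.3),
    start_temp: float = 25.0,
    plateau_delta: float = 3.0,
    plateau_hold: float = 500.0,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> list[tuple[StimulusProtocol, TemperatureTrace, SpikeTrain]]:
    """One TT unit stimulated once per ramp rate (separate recordings).

    Each recording ramps from ``start_temp`` by ``plateau_delta`` degC in
    the direction of the ramp, holds the plateau, and returns. Seeds for the
    trace noise and the spike generator are derived from ``seed`` and the
    ramp index.
    """
    out = []
    for i, r in enumerate(ramp_rates):
        plateau = start_temp + math.copysign(plateau_delta, r)
        proto = build_protocol(r, plateau, plateau_hold, start_temp=start_temp)
        trace = generate_temperature_trace(proto, noise_sd, seed=seed * 1009 + 2 * i)
        profile = tt_rate_profile(model, trace)
        train = simulate_spikes(profile, model.isi_shape, seed=seed * 1009 + 2 * i + 1)
        out.append((proto, trace, train))
    return out


def simulate_st_recording(
    model: STNeuronModel,
    ramp_rate: float = 0.01,
    start_temp: float = 23.0,
    plateau_temp: float = 37.0,
    plateau_hold: float = 500.0,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> tuple[StimulusProtocol, TemperatureTrace, SpikeTrain]:
    """One ST unit under a slow ramp spanning both activity plateaus."""
    proto = build_protocol(ramp_rate, plateau_temp, plateau_hold, start_temp=start_temp)
    trace = generate_temperature_trace(proto, noise_sd, seed=seed * 1013)
    profile = st_rate_profile(model, trace)
    train = simulate_spikes(profile, model.isi_shape, seed=seed * 1013 + 1)
    return proto, trace, train
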