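import math

import numpy as np
import pytest

from thermocode.spiketrain import instantaneous_frequency
from thermocode.synthetic import (
    RateProfile,
    STNeuronModel,
    TTNeuronModel,
    build_protocol,
    generate_temperature_trace,
    simulate_spikes,
    st_rate_profile,
    tt_rate_profile,
)


class TestBuildProtocol:
    def test_cooling_ramp_duration(self):
        p = build_protocol(-0.1, 20.0, 500.0, start_temp=25.0)
        assert p.ramp_duration == pytest.approx(50.0)
        assert p.plateau_hold == 500.0

    def test_fast_heating_ramp_duration(self):
        p = build_protocol(+0.43, 29.3, 500.0, start_temp=25.0)
        assert p.ramp_duration == pytest.approx(10.0)

    def test_sign_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sign"):
            build_protocol(+0.1, 20.0, 500.0, start_temp=25.0)

    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            build_protocol(0.0, 20.0, 500.0)

    def test_return_ramp_mirrors(self):
        p = build_protocol(-0.1, 20.0, 100.0, start_temp=25.0, pre_hold=10.0,
                           post_hold=10.0)
        t, y = p.knots()
        assert y[-1] == 25.0
        assert p.total_duration == pytest.approx(10 + 50 + 100 + 50 + 10)


class TestGenerateTrace:
    def test_noiseless_constant_hold(self):
        p = build_protocol(-0.1, 24.0, 10.0, pre_hold=5.0, post_hold=5.0)
        tr = generate_temperature_trace(p, noise_sd=0.0)
        hold = tr.temps[tr.times <= 5.0]
        assert np.all(hold == 25.0)

    def test_noiseless_ramp_step(self):
        p = build_protocol(-0.1, 20.0, 10.0, pre_hold=0.0, post_hold=0.0)
        tr = generate_temperature_trace(p, noise_sd=0.0)
        on_ramp = np.diff(tr.temps[: int(50 * 4)])
        assert np.allclose(on_ramp, -0.025, atol=1e-12)

    def test_noise_sd_recovered(self):
        p = build_protocol(-0.01, 20.0, 500.0, pre_hold=300.0, post_hold=300.0)
        tr = generate_temperature_trace(p, noise_sd=0.01, seed=3)
        clean = generate_temperature_trace(p, noise_sd=0.0)
        resid = tr.temps - clean.temps
        assert resid.size >= 4000
        assert np.std(resid) == pytest.approx(0.01, rel=0.2)

    def test_deterministic_under_seed(self):
        p = build_protocol(-0.1, 20.0, 50.0)
        a = generate_temperature_trace(p, noise_sd=0.01, seed=42)
        b = generate_temperature_trace(p, noise_sd=0.01, seed=42)
        assert np.array_equal(a.temps, b.temps)

    def test_negative_noise_rejected(self):
        p = build_protocol(-0.1, 20.0, 50.0)
        with pytest.raises(ValueError):
            generate_temperature_trace(p, noise_sd=-0.1)


class TestTTRateProfile:
    def test_steady_temperature_gives_resting_rate(self):
        model = TTNeuronModel(resting_rate=40.0)
        p = build_protocol(-0.1, 22.0, 100.0, pre_hold=60.0)
        tr = generate_temperature_trace(p, noise_sd=0.0)
        prof = tt_rate_profile(model, tr)
        pre = prof.rates[prof.bin_starts < 55]
        assert np.allclose(pre, 40.0, atol=1e-9)
        assert np.allclose(prof.nif[prof.bin_starts < 55], 100.0, atol=1e-9)

    def test_driven_nif_at_threshold_is_100(self):
        model = TTNeuronModel(threshold_rate=0.01)
        # at exactly theta the drive is zero (ln 1 = 0) and below it is None
        assert model.driven_nif(-0.01 * (1 + 1e-12)) == pytest.approx(100.0, abs=1e-6)
        assert model.driven_nif(-0.005) is None

    def test_driven_nif_at_e_times_theta(self):
        model = TTNeuronModel(gain_cool=60.0, threshold_rate=0.01)
        assert model.driven_nif(-0.01 * math.e) == pytest.approx(160.0, rel=1e-9)

    def test_nif_monotone_in_cooling_rate(self, tt_model):
        rates = -np.geomspace(0.021, 0.43, 30)
        nifs = [tt_model.driven_nif(r) for r in rates]
        assert np.all(np.diff(nifs) >= 0)  # stronger cooling -> higher nIF

    def test_silent_outside_working_range(self):
        model = TTNeuronModel(working_temp_low=21.0)
        p = build_protocol(-0.1, 18.0, 100.0, pre_hold=30.0)
        tr = generate_temperature_trace(p, noise_sd=0.0)
        prof = tt_rate_profile(model, tr)
        cold_bins = np.array(
            [i for i, s in enumerate(prof.bin_starts) if 120 < s < 180]
        )
        assert np.all(prof.rates[cold_bins] == 0.0)

    def test_heating_floor_never_negative(self):
        model = TTNeuronModel(gain_heat=200.0)
        assert model.driven_nif(0.43) == 0.0
        model = TTNeuronModel(gain_heat=200.0, heat_floor_nif=20.0)
        assert model.driven_nif(0.43) == 20.0


class TestSTRateProfile:
    def test_low_temperature_asymptote(self, st_model):
        t = st_model.midpoint_temp - 10 * st_model.width
        assert st_model.rate_at(t) == pytest.approx(st_model.rate_high, rel=1e-4)

    def test_midpoint_rate(self, st_model):
        mid = st_model.rate_at(st_model.midpoint_temp)
        assert mid == pytest.approx((st_model.rate_high + st_model.rate_low) / 2)

    def test_slope_at_midpoint(self):
        m = STNeuronModel(rate_high=50.0, rate_low=29.5, width=0.7885)
        h = 1e-5
        slope = (m.rate_at(30.0 + h) - m.rate_at(30.0 - h)) / (2 * h)
        assert slope == pytest.approx(-6.5, abs=0.01)
        assert slope == pytest.approx(-(50 - 29.5) / (4 * 0.7885), rel=1e-6)

    def test_rate_monotone_non_increasing(self, st_model):
        temps = np.linspace(20.0, 40.0, 200)
        rates = st_model.rate_at(temps)
        assert np.all(np.diff(rates) <= 0)


def flat_profile(rate: float, duration: float) -> RateProfile:
    starts = np.arange(duration)
    return RateProfile(bin_starts=starts, rates=np.full(int(duration), rate))


class TestSimulateSpikes:
    def test_zero_rate_empty(self):
        train = simulate_spikes(flat_profile(0.0, 100), isi_shape=1.0, seed=0)
        assert len(train) == 0

    def test_poisson_count_distribution(self):
        expected = 5000.0
        band = 3 * math.sqrt(expected)
        inside = 0
        for seed in range(50):
            train = simulate_spikes(flat_profile(50.0, 100), isi_shape=1.0, seed=seed)
            inside += abs(len(train) - expected) <= band
        assert inside >= 48

    def test_gamma_isi_cv(self):
        train = simulate_spikes(flat_profile(50.0, 150), isi_shape=4.0, seed=2)
        _, ifs = instantaneous_frequency(train)
        isi = 1.0 / ifs
        assert isi.size >= 5000
        cv = isi.std() / isi.mean()
        assert cv == pytest.approx(0.5, rel=0.1)

    def test_count_conservation(self):
        # expected 10^4 spikes; realized count within 5%
        train = simulate_spikes(flat_profile(50.0, 200), isi_shape=4.0, seed=9)
        assert len(train) == pytest.approx(10_000, rel=0.05)

    def test_determinism(self):
        a = simulate_spikes(flat_profile(30.0, 50), isi_shape=4.0, seed=21)
        b = simulate_spikes(flat_profile(30.0, 50), isi_shape=4.0, seed=21)
        assert np.array_equal(a.spike_times, b.spike_times)

    def test_spikes_follow_rate_modulation(self):
        rates = np.concatenate([np.full(50, 10.0), np.full(50, 80.0)])
        prof = RateProfile(bin_starts=np.arange(100.0), rates=rates)
        train = simulate_spikes(prof, isi_shape=4.0, seed=4)
        n_lo = np.sum(train.spike_times < 50.0)
        n_hi = np.sum(train.spike_times >= 50.0)
        assert n_lo == pytest.approx(500, rel=0.2)
        assert n_hi == pytest.approx(4000, rel=0.1)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_spikes(flat_profile(10.0, 30), isi_shape=0.5)
        with pytest.raises(ValueError):
            simulate_spikes(flat_profile(-1.0, 30), isi_shape=1.0)
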