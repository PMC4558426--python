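import math

import numpy as np
import pytest
from scipy import stats as sstats

from thermocode.spiketrain import BaselineStats, BinnedActivity
from thermocode.stimulus import BinnedStimulus
from thermocode.tt import (
    LN10,
    DoseResponsePoint,
    collect_points,
    detection_threshold,
    fit_dose_response,
    inverse_normal,
    jnd,
    resolving_power,
)

GAIN_LN = 60.0 / LN10  # 60 %/decade expressed per ln-unit


def make_baseline(noise_level: float = 10.0) -> BaselineStats:
    return BaselineStats(
        window=(50.0, 60.0),
        mean_nif=100.0,
        sd_nif=noise_level / 2,
        noise_level=noise_level,
        mean_rate_hz=40.0,
        n_bins=10,
    )


def points_on_line(rates, gain_ln=GAIN_LN, theta=0.01, direction="cooling"):
    return [
        DoseResponsePoint(
            log_rate=math.log(r),
            nif=100.0 + gain_ln * math.log(r / theta),
            direction=direction,
        )
        for r in rates
    ]


class TestCollectPoints:
    def _stim(self, rates, onset=0.0):
        return [BinnedStimulus(onset + i, 24.0, r) for i, r in enumerate(rates)]

    def _activity(self, nifs, onset=0.0):
        return [
            BinnedActivity(onset + i, 40.0, 40.0, nif=v) for i, v in enumerate(nifs)
        ]

    def test_all_within_noise_gives_empty(self):
        stim = self._stim([-0.05, -0.1, -0.2])
        act = self._activity([105.0, 95.0, 108.0])
        pts = collect_points(act, stim, make_baseline(10.0), onset=0.0)
        assert pts == []

    def test_supra_noise_cooling_bins_kept(self):
        stim = self._stim([-0.05, -0.1])
        act = self._activity([150.0, 160.0])
        pts = collect_points(act, stim, make_baseline(10.0), onset=0.0)
        assert len(pts) == 2
        assert pts[0].log_rate == pytest.approx(math.log(0.05))

    def test_direction_and_rate_floor_respected(self):
        stim = self._stim([-0.05, +0.1, -0.001])
        act = self._activity([150.0, 150.0, 150.0])
        pts = collect_points(
            act, stim, make_baseline(10.0), onset=0.0, min_abs_rate=0.02
        )
        assert len(pts) == 1  # heating bin and sub-floor bin excluded

    def test_heating_needs_suppression(self):
        stim = self._stim([+0.1, +0.2])
        act = self._activity([70.0, 95.0])
        pts = collect_points(
            act, stim, make_baseline(10.0), onset=0.0, direction="heating"
        )
        assert len(pts) == 1 and pts[0].nif == 70.0

    def test_window_limits(self):
        stim = self._stim([-0.1] * 300)
        act = self._activity([150.0] * 300)
        pts = collect_points(act, stim, make_baseline(10.0), onset=0.0, window=240.0)
        assert len(pts) == 240


class TestFitDoseResponse:
    def test_exact_line_recovered(self):
        pts = points_on_line([0.01, 0.022, 0.047, 0.1])
        fit = fit_dose_response(pts)
        assert fit.slope_decade == pytest.approx(60.0, abs=1e-9)
        assert fit.slope_ln * LN10 == fit.slope_decade
        assert fit.pearson_r == pytest.approx(1.0)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-9)
        assert fit.p_value < 0.05
        assert fit.qc_pass

    def test_weak_correlation_fails_qc(self, rng):
        x = rng.uniform(-4, -1, size=40)
        y = 130.0 + rng.normal(0, 10, size=40)  # no relation to x
        pts = [DoseResponsePoint(xi, yi, "cooling") for xi, yi in zip(x, y)]
        fit = fit_dose_response(pts)
        assert abs(fit.pearson_r) < 0.3
        assert not fit.qc_pass

    def test_heating_qc_requires_negative_r(self):
        pts = [
            DoseResponsePoint(math.log(r), 100.0 - 20.0 * math.log(r / 0.02), "heating")
            for r in (0.03, 0.06, 0.12, 0.3)
        ]
        fit = fit_dose_response(pts)
        assert fit.pearson_r == pytest.approx(-1.0)
        assert fit.qc_pass

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            fit_dose_response(points_on_line([0.01, 0.1, 0.3]))

    def test_narrow_span_rejected(self):
        with pytest.raises(ValueError, match="span"):
            fit_dose_response(points_on_line([0.1, 0.11, 0.12, 0.13]))

    def test_sigma_uses_n_minus_one(self):
        pts = points_on_line([0.01, 0.022, 0.047, 0.1])
        pts[0] = DoseResponsePoint(pts[0].log_rate, pts[0].nif + 8.0, "cooling")
        fit = fit_dose_response(pts)
        x = np.array([p.log_rate for p in pts])
        y = np.array([p.nif for p in pts])
        res = sstats.linregress(x, y)
        resid = y - res.intercept - res.slope * x
        assert fit.residual_sd == pytest.approx(
            math.sqrt(np.sum(resid**2) / (len(pts) - 1))
        )
        assert fit.stim_noise_level == pytest.approx(2 * fit.residual_sd)

    def test_regression_recovery_coverage(self, rng):
        """The fitted slope's 95% CI covers the true slope in >= 90% of runs."""
        n, sigma, true_b, true_a = 30, 5.0, 26.06, 220.0
        covered = 0
        n_sim = 200
        for _ in range(n_sim):
            x = rng.uniform(-4.6, -1.2, size=n)
            y = true_a + true_b * x + rng.normal(0, sigma, size=n)
            res = sstats.linregress(x, y)
            half = res.stderr * sstats.t.ppf(0.975, n - 2)
            covered += abs(res.slope - true_b) <= half
        assert covered >= 0.90 * n_sim


class TestResolvingPower:
    def test_paper_rounding_constant(self):
        assert inverse_normal(0.9, "paper") == pytest.approx(1.28)
        assert inverse_normal(0.9, "exact") == pytest.approx(1.2816, abs=5e-5)

    def test_zero_sigma_gives_zero(self):
        assert resolving_power(0.0, 26.0) == 0.0

    def test_worked_ratio(self):
        b = 26.06
        dx = resolving_power(0.1453 * b, b, gamma=0.9, phi_rounding="paper")
        assert dx == pytest.approx(0.372, abs=5e-4)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            resolving_power(1.0, 0.0)

    def test_linear_in_sigma_inverse_in_slope(self):
        for sigma in (1.0, 5.0, 12.0):
            for b in (10.0, 26.06, 80.0):
                dx = resolving_power(sigma, b)
                assert dx == pytest.approx(
                    sigma / 1.0 * resolving_power(1.0, b), rel=1e-12
                )
                assert dx == pytest.approx(
                    resolving_power(sigma, 1.0) / b, rel=1e-12
                )


class TestDetectionThreshold:
    def test_zero_noise_crossing_at_theta(self):
        fit = fit_dose_response(points_on_line([0.01, 0.022, 0.047, 0.1]))
        thr, clipped = detection_threshold(fit, make_baseline(0.0))
        assert thr == pytest.approx(-0.01, rel=1e-6)  # signed by direction
        assert not clipped

    def test_closed_form_with_noise(self):
        fit = fit_dose_response(points_on_line([0.01, 0.022, 0.047, 0.1]))
        thr, _ = detection_threshold(fit, make_baseline(10.0))
        assert abs(thr) == pytest.approx(0.01 * math.exp(10.0 / GAIN_LN), rel=1e-6)
        assert abs(thr) == pytest.approx(0.0147, abs=5e-5)

    def test_clipped_at_smallest_tested(self):
        fit = fit_dose_response(points_on_line([0.01, 0.022, 0.047, 0.1]))
        thr, clipped = detection_threshold(
            fit, make_baseline(0.0), smallest_tested=0.02
        )
        assert clipped and abs(thr) == 0.02

    def test_wrong_sign_slope_rejected(self):
        pts = [
            DoseResponsePoint(math.log(r), 80.0 + 10.0 * math.log(r), "heating")
            for r in (0.03, 0.06, 0.12, 0.3)
        ]
        fit = fit_dose_response(pts)
        with pytest.raises(ValueError, match="never crosses"):
            detection_threshold(fit, make_baseline(10.0))


class TestJND:
    @pytest.mark.parametrize(
        "rate, dx, expected",
        [(-0.1, 0.372, 0.037), (-0.047, 0.372, 0.017), (0.029, 0.275, 0.008)],
    )
    def test_worked_examples(self, rate, dx, expected):
        assert round(jnd(rate, dx), 3) == expected

    def test_negative_resolving_power_rejected(self):
        with pytest.raises(ValueError):
            jnd(0.1, -0.5)
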