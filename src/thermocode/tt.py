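"""Dose-response characterization of the transient-temperature (TT) neuron.

The TT-neuron is a thermal flux detector: its phasic response encodes the
temperature *changing rate*, not absolute temperature. Following the
Weber-Fechner law, response (nIF, %) is regressed on the natural log of the
stimulus magnitude |r| (degC/s). Three readouts characterize a unit:

* detection threshold — the stimulus magnitude at which the fitted line
  crosses the resting-activity noise band (baseline mean +/- 2 SD);
* differential sensitivity — the regression slope, reported per decade of
  stimulus intensity (slope_decade = slope_ln * ln 10);
* resolving power — dx = (2*sigma/|b|) * Phi^-1(gamma), the relative
  stimulus change needed for a response distinguishable from noise with
  probability gamma, where sigma is the residual SD about the regression
  (divisor n - 1) and b the slope.

Log-base convention: the regression is computed in natural log so that dx is
a dimensionless fraction of the stimulus and the just-noticeable difference
in absolute units is simply dx * |r| (first order). Sensitivity alone is
rescaled to %/decade for reporting. This is the only convention under which
the per-decade sensitivities and the dx worked examples (e.g. dx = 0.372 at
-0.1 degC/s giving a JND of 0.037 degC/s) are mutually consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sstats

from .spiketrain import BaselineStats, BinnedActivity
from .stimulus import BinnedStimulus

__all__ = [
    "DoseResponsePoint",
    "TTFitResult",
    "inverse_normal",
    "collect_points",
    "fit_dose_response",
    "resolving_power",
    "detection_threshold",
    "jnd",
    "LN10",
]

LN10 = math.log(10.0)


@dataclass(frozen=True)
class DoseResponsePoint:
    """One (ln |changing rate|, nIF) observation from a response bin."""

    log_rate: float  # ln(degC/s)
    nif: float  # %
    direction: str  # "cooling" | "heating"


@dataclass(frozen=True)
class TTFitResult:
    direction: str
    slope_ln: float  # % per ln-unit of |rate|
    slope_decade: float  # % per decade of |rate| (= slope_ln * ln 10)
    intercept: float  # % at ln|rate| = 0
    pearson_r: float
    p_value: float
    residual_sd: float  # sigma about the regression, divisor n - 1
    stim_noise_level: float  # 2 sigma
    n_points: int
    qc_pass: bool
    detection_threshold: float = float("nan")  # degC/s, signed by direction
    threshold_clipped: bool = False
    resolving_power: float = float("nan")  # dimensionless dx


def inverse_normal(gamma: float, rounding: str = "exact") -> float:
    """Phi^-1(gamma), the standard-normal quantile.

    ``rounding="paper"`` rounds to two decimals (1.28 at gamma = 0.9), the
    tabulated constant used in the original resolving-power computations;
    ``"exact"`` returns the full-precision quantile.
    """
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must lie in (0, 1)")
    q = float(sstats.norm.ppf(gamma))
    if rounding == "paper":
        return round(q, 2)
    if rounding == "exact":
        return q
    raise ValueError(f"unknown rounding mode {rounding!r}")


def collect_points(
    activity: list[BinnedActivity],
    stim: list[BinnedStimulus],
    baseline: BaselineStats,
    onset: float,
    window: float = 240.0,
    direction: str = "cooling",
    min_abs_rate: float = 0.0,
) -> list[DoseResponsePoint]:
    """Assemble dose-response points from the post-onset response window.

    Pairs each bin in [onset, onset + window) that carries an nIF with that
    bin's measured changing rate, keeping only bins that are both

    * *driven in the requested direction*: rate < 0 for cooling, > 0 for
      heating, with |rate| > ``min_abs_rate`` (a floor excluding plateau
      bins whose measured rate is only sensor noise), and
    * *response-bearing*: nIF above 100 + noise_level for cooling,
      below 100 - noise_level for heating.

    An empty result is returned (not raised) and flagged downstream.
    """
    if direction not in ("cooling", "heating"):
        raise ValueError(f"unknown direction {direction!r}")
    rate_by_start = {b.bin_start: b.changing_rate for b in stim}
    eps = 1e-9
    lo_t, hi_t = onset - eps, onset + window - eps
    points: list[DoseResponsePoint] = []
    for a in activity:
        if not (lo_t <= a.bin_start < hi_t) or not np.isfinite(a.nif):
            continue
        r = rate_by_start.get(a.bin_start)
        if r is None or abs(r) <= max(min_abs_rate, 0.0):
            continue
        if direction == "cooling":
            if r >= 0 or a.nif <= 100.0 + baseline.noise_level:
                continue
        else:
            if r <= 0 or a.nif >= 100.0 - baseline.noise_level:
                continue
        points.append(
            DoseResponsePoint(log_rate=math.log(abs(r)), nif=a.nif, direction=direction)
        )
    return points


def fit_dose_response(
    points: list[DoseResponsePoint],
    qc_p: float = 0.05,
    qc_r: float = 0.3,
) -> TTFitResult:
    """Ordinary least squares of nIF on ln|rate|, with quality control.

    Requires at least 4 points spanning at least 0.5 ln-units of stimulus.
    The residual SD is sigma = sqrt(sum(eps^2) / (n - 1)) and the stimulus
    noise level is its two-fold value (the 2 SD band about the regression).
    QC passes when the slope is significant (p < ``qc_p``) and the Pearson
    correlation is at least moderate in the direction-appropriate sense
    (r > ``qc_r`` for cooling, r < -``qc_r`` for heating).
    """
    if len(points) < 4:
        raise ValueError(f"need >= 4 dose-response points, got {len(points)}")
    directions = {p.direction for p in points}
    if len(directions) != 1:
        raise ValueError("points mix directions")
    direction = directions.pop()
    x = np.array([p.log_rate for p in points])
    y = np.array([p.nif for p in points])
    span = float(x.max() - x.min())
    if span < 0.5:
        raise ValueError(f"stimulus span {span:.3f} ln-units < 0.5")
    res = sstats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    sigma = float(np.sqrt(np.sum(resid**2) / (len(points) - 1)))
    r = float(res.rvalue)
    p = float(res.pvalue)
    if direction == "cooling":
        qc = (p < qc_p) and (r > qc_r)
    else:
        qc = (p < qc_p) and (r < -qc_r)
    return TTFitResult(
        direction=direction,
        slope_ln=float(res.slope),
        slope_decade=float(res.slope) * LN10,
        intercept=float(res.intercept),
        pearson_r=r,
        p_value=p,
        residual_sd=sigma,
        stim_noise_level=2.0 * sigma,
        n_points=len(points),
        qc_pass=bool(qc),
    )


def resolving_power(
    residual_sd: float,
    slope_ln: float,
    gamma: float = 0.9,
    phi_rounding: str = "exact",
) -> float:
    """Resolving power dx = (2 * sigma / |b|) * Phi^-1(gamma).

    The relative stimulus change needed for the response to differ from the
    noise band about the regression with probability ``gamma``. Dimensionless
    when the regression is on ln|rate| (then the absolute just-noticeable
    difference at stimulus r is dx * |r|, see :func:`jnd`).
    """
    if slope_ln == 0:
        raise ValueError("zero slope: resolving power undefined")
    if not 0.5 < gamma < 1.0:
        raise ValueError("gamma must lie in (0.5, 1)")
    if residual_sd < 0:
        raise ValueError("residual_sd must be >= 0")
    return (2.0 * residual_sd / abs(slope_ln)) * inverse_normal(gamma, phi_rounding)


def detection_threshold(
    fit: TTFitResult,
    baseline: BaselineStats,
    smallest_tested: float | None = None,
) -> tuple[float, bool]:
    """Stimulus magnitude where the fitted line leaves the resting noise band.

    Solves 100 + noise_level = intercept + slope * ln|r| for cooling
    (100 - noise_level for heating) and returns (threshold, clipped) with the
    threshold signed by direction (negative for cooling). When the crossing
    lies below the smallest tested stimulus the threshold is clipped there
    and flagged: the line was never observed below that intensity.
    """
    if fit.direction == "cooling":
        if fit.slope_ln <= 0:
            raise ValueError("cooling fit with non-positive slope never crosses the band")
        x = (100.0 + baseline.noise_level - fit.intercept) / fit.slope_ln
        sign = -1.0
    else:
        if fit.slope_ln >= 0:
            raise ValueError("heating fit with non-negative slope never crosses the band")
        x = (100.0 - baseline.noise_level - fit.intercept) / fit.slope_ln
        sign = 1.0
    mag = math.exp(x)
    clipped = False
    if smallest_tested is not None and mag < smallest_tested:
        mag = smallest_tested
        clipped = True
    return sign * mag, clipped


def jnd(stimulus_rate: float, resolving_power: float) -> float:
    """Just-noticeable stimulus difference at a given driving rate.

    First-order conversion of the log-scale resolving power into absolute
    stimulus units: returns dx * |stimulus_rate| (degC/s, magnitude). E.g. a
    unit driven at -0.1 degC/s with dx = 0.372 resolves changes of
    0.037 degC/s.
    """
    if resolving_power < 0:
        raise ValueError("resolving_power must be >= 0")
    return resolving_power * abs(stimulus_rate)


def finalize_tt_fit(
    fit: TTFitResult,
    baseline: BaselineStats,
    gamma: float = 0.9,
    phi_rounding: str = "exact",
    smallest_tested: float | None = None,
) -> TTFitResult:
    """Fill threshold and resolving power on a fitted result (QC permitting)."""
    if not fit.qc_pass:
        return fit
    thr, clipped = detection_threshold(fit, baseline, smallest_tested)
    dx = resolving_power(fit.residual_sd, fit.slope_ln, gamma, phi_rounding)
    return replace(
        fit, detection_threshold=thr, threshold_clipped=clipped, resolving_power=dx
    )
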