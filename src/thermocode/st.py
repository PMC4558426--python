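"""Characterization of the steady-temperature (ST) neuron.

The ST-neuron fires at two distinct sustained activity plateaus (around
50 APs/s at low and 30 APs/s at high temperature) joined by a sigmoidal
transition centered near 30 degC. Its mean rate in 1-s windows is fitted
with a decreasing four-parameter logistic by Gauss-Newton iteration:

    rate(T) = rate_low + (rate_high - rate_low) / (1 + exp((T - T0) / w))

The slope at the turning point T0, -(rate_high - rate_low)/(4 w) in
APs/degC, is the neuron's peak sensitivity. The working range is bounded by
the 10% departure rule from the two plateaus, and the resolving power in
degC comes from a linear regression within +/-1 degC of the turning point
(where the logistic is nearly linear), using the same 2-sigma/|b| * Phi^-1
statistic as the flux analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sstats

from .tt import inverse_normal

__all__ = [
    "STFitResult",
    "logistic",
    "fit_sigmoid",
    "working_range",
    "st_resolving_power",
    "plateau_comparison",
]


@dataclass(frozen=True)
class STFitResult:
    rate_high: float  # APs/s, low-temperature plateau
    rate_low: float  # APs/s, high-temperature plateau
    midpoint_temp: float  # degC (turning point T0)
    width: float  # degC (logistic scale w)
    slope_at_midpoint: float  # APs/degC, = -(rate_high - rate_low)/(4 w)
    converged: bool
    n_iter: int
    sse: float
    working_low: float = float("nan")  # degC
    working_high: float = float("nan")  # degC
    working_rule: str = ""
    resolving_power_c: float = float("nan")  # degC
    plateau_drop_pct: float = float("nan")  # %


def logistic(
    temp: np.ndarray | float,
    rate_high: float,
    rate_low: float,
    midpoint_temp: float,
    width: float,
) -> np.ndarray | float:
    """Decreasing logistic rate model, vectorized over temperature."""
    u = (np.asarray(temp, dtype=float) - midpoint_temp) / width
    out = rate_low + (rate_high - rate_low) / (1.0 + np.exp(u))
    return float(out) if np.isscalar(temp) else out


def _initial_guess(temps: np.ndarray, rates: np.ndarray) -> np.ndarray:
    order = np.argsort(temps)
    t, y = temps[order], rates[order]
    n = t.size
    k = max(3, n // 10)
    hi = float(np.mean(y[:k]))  # cool end
    lo = float(np.mean(y[-k:]))  # warm end
    if hi <= lo:  # flat or inverted data; keep the fitter well-posed
        hi = float(np.max(y))
        lo = float(np.min(y))
        if hi <= lo:
            hi = lo + 1.0
    # lightly smooth (edge-renormalized), then find where the rate crosses
    # given span fractions
    win = max(3, n // 50) | 1
    kernel = np.ones(win)
    ys = np.convolve(y, kernel, mode="same") / np.convolve(
        np.ones(n), kernel, mode="same"
    )

    def crossing(frac: float) -> float:
        level = lo + frac * (hi - lo)
        below = ys <= level
        idx = int(np.argmax(below)) if below.any() else n - 1
        return float(t[idx])

    t0 = crossing(0.5)
    w = abs(crossing(0.25) - crossing(0.75)) / 4.0
    if not np.isfinite(w) or w <= 0:
        w = (t[-1] - t[0]) / 10.0
    return np.array([hi, lo, t0, max(w, 1e-3)])


def fit_sigmoid(
    temps: np.ndarray,
    rates: np.ndarray,
    max_iter: int = 200,
    grad_tol: float = 1e-8,
) -> STFitResult:
    """Fit the decreasing logistic to (temperature, mean rate) bins.

    Gauss-Newton with step halving on the residual sum of squares;
    initialization from the data (plateau levels from the extreme 10% of
    the temperature range, T0 from the mid-span crossing, w from the
    quarter-span crossings). Convergence is declared when the gradient
    infinity-norm drops below ``grad_tol * max(1, sse)``; hitting
    ``max_iter`` returns ``converged=False`` rather than raising, so a
    stubborn unit never aborts a cohort run.

    Requires >= 12 bins spanning >= 4 degC with data on both sides of the
    apparent transition.
    """
    temps = np.asarray(temps, dtype=float)
    rates = np.asarray(rates, dtype=float)
    mask = np.isfinite(temps) & np.isfinite(rates)
    temps, rates = temps[mask], rates[mask]
    if temps.size < 12:
        raise ValueError(f"need >= 12 bins, got {temps.size}")
    if temps.max() - temps.min() < 4.0:
        raise ValueError("temperature span < 4 degC")
    p = _initial_guess(temps, rates)
    if not (temps.min() < p[2] < temps.max()):
        raise ValueError("data do not straddle the apparent transition")

    def model_and_jac(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        hi, lo, t0, w = p
        u = (temps - t0) / w
        s = 1.0 / (1.0 + np.exp(u))  # 1 at cool end, 0 at warm end
        f = lo + (hi - lo) * s
        d = (hi - lo) * s * (1.0 - s)
        J = np.column_stack([s, 1.0 - s, d / w, d * u / w])
        return f, J

    f, J = model_and_jac(p)
    resid = rates - f
    sse = float(resid @ resid)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad = J.T @ resid
        if np.max(np.abs(grad)) < grad_tol * max(1.0, sse):
            converged = True
            break
        step, *_ = np.linalg.lstsq(J, resid, rcond=None)
        # step halving: never accept an increase in SSE
        scale = 1.0
        for _ in range(30):
            trial = p + scale * step
            if trial[3] > 0:
                f_t, J_t = model_and_jac(trial)
                r_t = rates - f_t
                sse_t = float(r_t @ r_t)
                if sse_t <= sse:
                    p, f, J, resid, sse = trial, f_t, J_t, r_t, sse_t
                    break
            scale *= 0.5
        else:
            converged = np.max(np.abs(J.T @ resid)) < math.sqrt(grad_tol) * max(1.0, sse)
            break

    hi, lo, t0, w = (float(v) for v in p)
    if hi < lo:  # same curve re-labelled; normalize to rate_high > rate_low
        hi, lo, w = lo, hi, -w
    if hi <= lo or w <= 0:
        converged = False
    return STFitResult(
        rate_high=hi,
        rate_low=lo,
        midpoint_temp=t0,
        width=w,
        slope_at_midpoint=-(hi - lo) / (4.0 * w),
        converged=converged,
        n_iter=it,
        sse=sse,
    )


def working_range(fit: STFitResult, rule: str = "literal") -> tuple[float, float]:
    """Temperature bounds of the neuron's working range (10% rule).

    ``rule="literal"``: boundary activities are 0.90 * rate_high (departure
    from the high plateau) and 1.10 * rate_low (departure from the low
    plateau). ``rule="span"``: boundaries are 10% of the plateau span inside
    each plateau, which is symmetric about T0 and remains defined when
    rate_low approaches 0 (the literal rule degenerates there: 1.10 * 0 is
    never attained).

    Each boundary activity is inverted through the fitted logistic:
    T(a) = T0 + w * ln((rate_high - a) / (a - rate_low)).
    """
    if not fit.converged:
        raise ValueError("working range requires a converged fit")
    hi, lo = fit.rate_high, fit.rate_low
    if rule == "literal":
        if lo <= 0:
            raise ValueError("literal 10% rule degenerate at rate_low <= 0")
        a_cool, a_warm = 0.90 * hi, 1.10 * lo
    elif rule == "span":
        span = hi - lo
        a_cool, a_warm = hi - 0.10 * span, lo + 0.10 * span
    else:
        raise ValueError(f"unknown working-range rule {rule!r}")
    for a in (a_cool, a_warm):
        if not lo < a < hi:
            raise ValueError(
                f"boundary activity {a:.3f} outside the open plateau interval "
                f"({lo:.3f}, {hi:.3f})"
            )

    def invert(a: float) -> float:
        return fit.midpoint_temp + fit.width * math.log((hi - a) / (a - lo))

    return invert(a_cool), invert(a_warm)


def st_resolving_power(
    temps: np.ndarray,
    rates: np.ndarray,
    fit: STFitResult,
    half_window: float = 1.0,
    gamma: float = 0.9,
    phi_rounding: str = "exact",
) -> float:
    """Resolving power for steady temperature, in degC.

    Linear regression of mean rate on temperature over the bins within
    ``half_window`` degC of the turning point (where sensitivity is highest
    and the logistic nearly linear), then dx = (2*sigma/|b|) * Phi^-1(gamma)
    with sigma the residual SD (divisor n - 1).
    """
    temps = np.asarray(temps, dtype=float)
    rates = np.asarray(rates, dtype=float)
    mask = (
        np.isfinite(temps)
        & np.isfinite(rates)
        & (np.abs(temps - fit.midpoint_temp) <= half_window)
    )
    if mask.sum() < 4:
        raise ValueError(
            f"only {int(mask.sum())} bins within +/-{half_window} degC of the turning point"
        )
    x, y = temps[mask], rates[mask]
    res = sstats.linregress(x, y)
    if res.slope == 0:
        raise ValueError("zero slope in the turning-point window")
    resid = y - (res.intercept + res.slope * x)
    sigma = float(np.sqrt(np.sum(resid**2) / (x.size - 1)))
    return (2.0 * sigma / abs(float(res.slope))) * inverse_normal(gamma, phi_rounding)


def plateau_comparison(
    rates_low_temp: np.ndarray,
    rates_high_temp: np.ndarray,
    paired: bool = True,
) -> tuple[float, float]:
    """Compare the two sustained activity levels across a cohort.

    Inputs are per-recording mean rates below the working range (low
    temperature, high activity) and above it. Returns (drop_pct, p_value)
    where drop_pct = 100 * (mean_low_temp - mean_high_temp) / mean_low_temp
    and the p-value comes from a Wilcoxon signed-rank test when paired by
    recording (rank-sum otherwise), two-sided.
    """
    a = np.asarray(rates_low_temp, dtype=float)
    b = np.asarray(rates_high_temp, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each activity-level list needs >= 3 values")
    if paired and a.size != b.size:
        raise ValueError("paired comparison requires equal-length lists")
    mean_a = float(np.mean(a))
    drop = 100.0 * (mean_a - float(np.mean(b))) / mean_a
    if paired:
        if np.allclose(a, b):
            p = 1.0
        else:
            p = float(sstats.wilcoxon(a, b, zero_method="zsplit").pvalue)
    else:
        p = float(sstats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return drop, p


def finalize_st_fit(
    temps: np.ndarray,
    rates: np.ndarray,
    fit: STFitResult,
    rule: str = "literal",
    half_window: float = 1.0,
    gamma: float = 0.9,
    phi_rounding: str = "exact",
) -> STFitResult:
    """Fill working range, resolving power and plateau drop on a fit."""
    wl, wh = working_range(fit, rule)
    dx = st_resolving_power(temps, rates, fit, half_window, gamma, phi_rounding)
    drop = 100.0 * (fit.rate_high - fit.rate_low) / fit.rate_high
    return replace(
        fit,
        working_low=wl,
        working_high=wh,
        working_rule=rule,
        resolving_power_c=dx,
        plateau_drop_pct=drop,
    )
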