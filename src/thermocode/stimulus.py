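"""Conditioning of raw temperature traces into binned stimulus descriptors.

The stimulus record is a thermocouple trace sampled nominally at 4 Hz. All
downstream analysis works on 1-s windows, each described by its mean
temperature and its temperature changing rate (the within-bin least-squares
slope, in degC/s). A Gaussian smoothing pass compensates for sensor noise
before binning, and a simple run-length detector locates stimulus onset when
the stimulation protocol is not known a priori.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "TemperatureTrace",
    "BinnedStimulus",
    "NoStimulusError",
    "gauss_smooth",
    "bin_stimulus",
    "detect_onset",
]


class NoStimulusError(ValueError):
    """Raised when no bin run satisfies the onset-detection criterion."""


@dataclass(frozen=True)
class TemperatureTrace:
    """A timestamped temperature record.

    Parameters
    ----------
    times : array of float
        Sample times in seconds, strictly increasing.
    temps : array of float
        Temperature in degC, same length as ``times``.
    """

    times: np.ndarray
    temps: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        temps = np.asarray(self.temps, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "temps", temps)
        if times.ndim != 1 or temps.ndim != 1:
            raise ValueError("times and temps must be 1-D")
        if times.size != temps.size:
            raise ValueError("times and temps must have equal length")
        if times.size < 2:
            raise ValueError("a trace needs at least 2 samples")
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(temps))):
            raise ValueError("trace contains non-finite values")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def sampling_interval(self) -> float:
        """Median inter-sample interval in seconds."""
        return float(np.median(np.diff(self.times)))


@dataclass(frozen=True)
class BinnedStimulus:
    """One 1-s stimulus window: mean temperature and changing rate."""

    bin_start: float
    mean_temp: float
    changing_rate: float


def gauss_smooth(trace: TemperatureTrace, sigma: float) -> TemperatureTrace:
    """Gaussian smoothing of a temperature trace.

    The kernel SD ``sigma`` is given in seconds and converted to samples via
    the trace's sampling interval. The kernel is truncated at +/-4 sigma and
    renormalized over the available samples at the edges, so constant traces
    are preserved exactly and the output never leaves the input's range.
    ``sigma = 0`` is the identity.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    sigma_samples = sigma / trace.sampling_interval
    if sigma_samples < 1e-3:  # kernel narrower than a millisample: identity
        return trace
    num = gaussian_filter1d(
        trace.temps, sigma_samples, mode="constant", cval=0.0, truncate=4.0
    )
    den = gaussian_filter1d(
        np.ones_like(trace.temps), sigma_samples, mode="constant", cval=0.0, truncate=4.0
    )
    return TemperatureTrace(trace.times, num / den)


def bin_stimulus(
    trace: TemperatureTrace,
    bin_width: float = 1.0,
    anchor: float | None = None,
) -> list[BinnedStimulus]:
    """Partition a trace into contiguous half-open bins of ``bin_width`` s.

    Each bin reports the arithmetic mean temperature of its samples and the
    least-squares slope of temperature against time over those samples
    (exact on noiseless ramps). Bins holding fewer than 2 samples are
    dropped.

    Parameters
    ----------
    anchor : float, optional
        A time the bin grid must pass through; the grid is extended backwards
        and forwards from the anchor to cover the whole trace. Defaults to
        the first sample time.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    t = trace.times
    if trace.duration < 2 * bin_width:
        raise ValueError("trace shorter than two bin widths")
    if anchor is None:
        anchor = float(t[0])
    # first grid edge at or before the first sample
    k0 = math.ceil((anchor - t[0]) / bin_width - 1e-9)
    first = anchor - k0 * bin_width
    n_bins = math.ceil((t[-1] - first) / bin_width + 1e-9)
    edges = first + bin_width * np.arange(n_bins + 1)
    idx = np.searchsorted(t, edges, side="left")

    out: list[BinnedStimulus] = []
    temps = trace.temps
    for i in range(n_bins):
        lo, hi = idx[i], idx[i + 1]
        if hi - lo < 2:
            continue
        tt = t[lo:hi]
        yy = temps[lo:hi]
        tc = tt - tt.mean()
        slope = float(np.dot(tc, yy) / np.dot(tc, tc))
        out.append(
            BinnedStimulus(
                bin_start=float(edges[i]),
                mean_temp=float(yy.mean()),
                changing_rate=slope,
            )
        )
    return out


def detect_onset(
    binned: list[BinnedStimulus],
    rate_floor: float,
    run_length: int = 3,
) -> float:
    """Locate stimulus onset from binned changing rates.

    Returns the start time of the first bin whose absolute changing rate
    reaches ``rate_floor`` and which begins a run of at least ``run_length``
    consecutive such bins (the run requirement suppresses single-bin noise
    triggers).
    """
    if rate_floor <= 0:
        raise ValueError("rate_floor must be positive")
    if run_length < 1:
        raise ValueError("run_length must be >= 1")
    hot = [abs(b.changing_rate) >= rate_floor for b in binned]
    for i in range(len(binned) - run_length + 1):
        if all(hot[i : i + run_length]):
            return binned[i].bin_start
    raise NoStimulusError("no stimulus found")
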