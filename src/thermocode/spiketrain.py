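"""Per-bin activity measures from sorted spike times.

Two rate measures are used downstream, matching how the two neuron types are
analyzed. The instantaneous frequency (IF) is the reciprocal of an
inter-spike interval; its per-bin median, normalized to a 10-s pre-stimulus
baseline (nIF, in percent), quantifies the phasic response of the
flux-detecting neuron. The mean rate (spike count per 1-s bin) gives
complete per-bin coverage and quantifies the steady-temperature neuron,
which lacks a phasic response.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .stimulus import BinnedStimulus

__all__ = [
    "SpikeTrain",
    "BinnedActivity",
    "BaselineStats",
    "instantaneous_frequency",
    "bin_activity",
    "normalize_nif",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times of one unit, in seconds."""

    spike_times: np.ndarray

    def __post_init__(self) -> None:
        st = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", st)
        if st.ndim != 1:
            raise ValueError("spike_times must be 1-D")
        if not np.all(np.isfinite(st)):
            raise ValueError("spike_times contains non-finite values")
        if st.size >= 2:
            d = np.diff(st)
            if np.any(d < 0):
                bad = int(np.argmax(d < 0))
                raise ValueError(f"spike_times not sorted at index {bad + 1}")
            if np.any(d == 0):
                bad = int(np.argmax(d == 0))
                raise ValueError(f"duplicate spike time at index {bad + 1}")

    def __len__(self) -> int:
        return int(self.spike_times.size)


@dataclass(frozen=True)
class BinnedActivity:
    """Activity of one unit in one 1-s window.

    ``median_if`` is NaN when no IF sample falls in the bin (the median of an
    empty set is undefined; it is deliberately not coerced to 0, which would
    bias suppression fits). ``nif`` is NaN until a baseline has been applied.
    """

    bin_start: float
    median_if: float
    mean_rate: float
    nif: float = float("nan")


@dataclass(frozen=True)
class BaselineStats:
    """Resting-activity statistics over the pre-stimulus baseline window.

    ``noise_level`` is twice the SD of the baseline-window nIF — the noise
    measure against which responses are judged. ``mean_rate_hz`` is the raw
    resting activity (mean of the baseline-window median IFs, in Hz).
    """

    window: tuple[float, float]
    mean_nif: float
    sd_nif: float
    noise_level: float
    mean_rate_hz: float
    n_bins: int


def instantaneous_frequency(train: SpikeTrain) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous frequency: reciprocal inter-spike intervals.

    Each consecutive spike pair (t_i, t_{i+1}) yields IF = 1/(t_{i+1} - t_i),
    timestamped at the second spike (the instant the measurement becomes
    available). Returns ``(timestamps, ifs)``; both empty for fewer than two
    spikes.
    """
    st = train.spike_times
    if st.size < 2:
        return np.empty(0), np.empty(0)
    isi = np.diff(st)
    return st[1:], 1.0 / isi


def bin_activity(
    train: SpikeTrain,
    bins: list[BinnedStimulus],
    bin_width: float = 1.0,
    if_assignment: str = "second",
) -> list[BinnedActivity]:
    """Median IF and mean rate of a unit over the stimulus bin grid.

    ``median_if`` is NaN for bins with no IF sample; ``mean_rate`` is the
    spike count in the bin divided by the bin width. ``if_assignment``
    stamps each IF at the interval's ``"second"`` spike (default: the
    instant the measurement becomes available), ``"first"`` spike, or
    ``"midpoint"`` — a convention, since an interval may straddle a bin
    edge.
    """
    if_times, ifs = instantaneous_frequency(train)
    if if_assignment == "first":
        if_times = train.spike_times[:-1] if len(train) >= 2 else if_times
    elif if_assignment == "midpoint":
        if len(train) >= 2:
            if_times = 0.5 * (train.spike_times[:-1] + train.spike_times[1:])
    elif if_assignment != "second":
        raise ValueError(f"unknown if_assignment {if_assignment!r}")
    st = train.spike_times
    out: list[BinnedActivity] = []
    for b in bins:
        lo, hi = b.bin_start, b.bin_start + bin_width
        n_spikes = int(
            np.searchsorted(st, hi, side="left") - np.searchsorted(st, lo, side="left")
        )
        i0 = np.searchsorted(if_times, lo, side="left")
        i1 = np.searchsorted(if_times, hi, side="left")
        med = float(np.median(ifs[i0:i1])) if i1 > i0 else float("nan")
        out.append(
            BinnedActivity(
                bin_start=b.bin_start,
                median_if=med,
                mean_rate=n_spikes / bin_width,
            )
        )
    return out


def normalize_nif(
    activity: list[BinnedActivity],
    onset: float,
    baseline_len: float = 10.0,
    min_bins: int = 5,
) -> tuple[list[BinnedActivity], BaselineStats]:
    """Normalize median IFs to the pre-stimulus baseline (nIF, percent).

    The baseline is the mean median IF over the ``baseline_len`` seconds
    before ``onset``; every bin's nIF is 100 * median_if / baseline, so the
    baseline-window nIF averages 100% by construction. The baseline window's
    nIF SD defines the noise level as its two-fold value.

    Raises if fewer than ``min_bins`` baseline bins carry a median IF, or if
    the baseline is zero — such recordings are unanalyzable rather than
    silently extrapolated.
    """
    eps = 1e-9
    base_vals = [
        a.median_if
        for a in activity
        if onset - baseline_len - eps <= a.bin_start < onset - eps
        and np.isfinite(a.median_if)
    ]
    if len(base_vals) < min_bins:
        raise ValueError(
            f"only {len(base_vals)} baseline bins with spikes; need >= {min_bins}"
        )
    baseline = float(np.mean(base_vals))
    if baseline <= 0:
        raise ValueError("baseline activity is zero")
    normalized = [
        replace(a, nif=100.0 * a.median_if / baseline) if np.isfinite(a.median_if) else a
        for a in activity
    ]
    base_nif = 100.0 * np.asarray(base_vals) / baseline
    sd = float(np.std(base_nif, ddof=1))
    stats = BaselineStats(
        window=(onset - baseline_len, onset),
        mean_nif=float(np.mean(base_nif)),
        sd_nif=sd,
        noise_level=2.0 * sd,
        mean_rate_hz=baseline,
        n_bins=len(base_vals),
    )
    return normalized, stats
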