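"""Per-recording orchestration, cohort summaries, file I/O and reports.

A Recording pairs a temperature trace with one unit's sorted spike times.
``run_recording`` chains the stages (smooth -> bin -> onset -> activity ->
TT and/or ST characterization) under one configuration; cohort helpers
aggregate per-unit results into summary tables, exploratory correlations
and group comparisons, and write deterministic reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sstats

from . import st as st_mod
from . import tt as tt_mod
from .spiketrain import BaselineStats, SpikeTrain, bin_activity, normalize_nif
from .st import STFitResult
from .stimulus import (
    BinnedStimulus,
    NoStimulusError,
    TemperatureTrace,
    bin_stimulus,
    detect_onset,
    gauss_smooth,
)
from .tt import TTFitResult

__all__ = [
    "AnalysisConfig",
    "Recording",
    "RecordingResult",
    "StageError",
    "read_recording",
    "run_recording",
    "analyze_tt_unit",
    "analyze_cohort",
    "cohort_summary",
    "write_report",
]

log = logging.getLogger("thermocode")


class StageError(RuntimeError):
    """A pipeline stage failed for one unit; carries unit id and stage name."""

    def __init__(self, unit_id: str, stage: str, cause: Exception):
        super().__init__(f"[{unit_id}] stage {stage!r}: {cause}")
        self.unit_id = unit_id
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisConfig:
    """All tunable analysis parameters with their defaults.

    smoothing_sigma      Gaussian kernel SD for the temperature trace, s
    bin_width            analysis window width, s
    baseline_len         pre-stimulus baseline window, s
    response_window      post-onset window for the flux dose-response, s
    gamma                required detection probability for resolving power
    phi_rounding         "exact" | "paper" (Phi^-1(0.9) as 1.2816 vs 1.28)
    working_range_rule   "literal" | "span" 10% rule for the ST working range
    qc_p, qc_r           regression QC: p-value and Pearson-r cutoffs
    onset_rate_floor     minimum |changing rate| for onset detection, degC/s
    onset_run_length     consecutive supra-floor bins required at onset
    min_abs_rate         |rate| floor for dose-response bins (None -> onset floor)
    st_half_window       half-width of the turning-point regression window, degC
    """

    smoothing_sigma: float = 0.5
    bin_width: float = 1.0
    baseline_len: float = 10.0
    response_window: float = 240.0
    gamma: float = 0.9
    phi_rounding: str = "exact"
    working_range_rule: str = "literal"
    qc_p: float = 0.05
    qc_r: float = 0.3
    onset_rate_floor: float = 0.02
    onset_run_length: int = 3
    min_abs_rate: float | None = None
    st_half_window: float = 1.0

    @property
    def rate_floor_points(self) -> float:
        return self.onset_rate_floor if self.min_abs_rate is None else self.min_abs_rate

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def sha256(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class Recording:
    unit_id: str
    neuron_class: str  # "TT" | "ST" | "unknown"
    trace: TemperatureTrace
    train: SpikeTrain
    protocol_onset: float | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class RecordingResult:
    unit_id: str
    neuron_class: str
    tt: dict[str, TTFitResult] = field(default_factory=dict)  # by direction
    st: STFitResult | None = None
    baseline: BaselineStats | None = None
    errors: list[str] = field(default_factory=list)


def read_recording(
    temperature_csv: str | Path,
    spikes_csv: str | Path,
    unit_id: str | None = None,
    neuron_class: str = "unknown",
    sidecar_json: str | Path | None = None,
) -> Recording:
    """Load and validate one recording from its CSV pair.

    The temperature file needs columns ``time_s, temp_c``; the spikes file a
    ``spike_time_s`` column. Times are in seconds. Rejects NaN values,
    unsorted spikes (naming the offending index), and spikes outside the
    trace span beyond one sampling interval. A temperature gap longer than 3
    sampling intervals is logged as a warning and analysis proceeds. A
    sidecar JSON may supply ``unit_id``, ``neuron_class``, ``onset`` and is
    kept as metadata.
    """
    temperature_csv, spikes_csv = Path(temperature_csv), Path(spikes_csv)
    tdf = pd.read_csv(temperature_csv, float_precision="round_trip")
    for col in ("time_s", "temp_c"):
        if col not in tdf.columns:
            raise ValueError(f"{temperature_csv.name}: missing column {col!r}")
    if tdf.empty:
        raise ValueError(f"{temperature_csv.name}: empty file")
    if tdf[["time_s", "temp_c"]].isna().any().any():
        raise ValueError(f"{temperature_csv.name}: NaN values present")
    sdf = pd.read_csv(spikes_csv, float_precision="round_trip")
    if "spike_time_s" not in sdf.columns:
        raise ValueError(f"{spikes_csv.name}: missing column 'spike_time_s'")
    if sdf["spike_time_s"].isna().any():
        raise ValueError(f"{spikes_csv.name}: NaN values present")

    spikes = sdf["spike_time_s"].to_numpy(dtype=float)
    if spikes.size >= 2:
        d = np.diff(spikes)
        if np.any(d <= 0):
            bad = int(np.argmax(d <= 0)) + 1
            raise ValueError(f"{spikes_csv.name}: spikes unsorted at row index {bad}")

    trace = TemperatureTrace(
        tdf["time_s"].to_numpy(dtype=float), tdf["temp_c"].to_numpy(dtype=float)
    )
    dt = trace.sampling_interval
    gaps = np.diff(trace.times)
    if np.any(gaps > 3 * dt):
        n_gaps = int(np.sum(gaps > 3 * dt))
        log.warning(
            "%s: %d temperature gap(s) > 3 sampling intervals; affected bins "
            "will carry fewer samples",
            temperature_csv.name,
            n_gaps,
        )
    if spikes.size and (
        spikes[0] < trace.times[0] - dt or spikes[-1] > trace.times[-1] + dt
    ):
        raise ValueError(f"{spikes_csv.name}: spike times outside the trace span")

    meta: dict = {}
    protocol_onset = None
    if sidecar_json is not None:
        with open(sidecar_json) as fh:
            meta = json.load(fh)
        unit_id = unit_id or meta.get("unit_id")
        neuron_class = meta.get("neuron_class", neuron_class)
        protocol_onset = meta.get("onset")
    if unit_id is None:
        unit_id = temperature_csv.stem.replace("_temperature", "")
    return Recording(
        unit_id=unit_id,
        neuron_class=neuron_class,
        trace=trace,
        train=SpikeTrain(spikes),
        protocol_onset=protocol_onset,
        meta=meta,
    )


def _prepare(rec: Recording, config: AnalysisConfig):
    """Smooth, bin (onset-anchored), locate onset, bin activity."""
    smoothed = gauss_smooth(rec.trace, config.smoothing_sigma)
    stim = bin_stimulus(smoothed, config.bin_width)
    if rec.protocol_onset is not None:
        onset = float(rec.protocol_onset)
    else:
        onset = detect_onset(stim, config.onset_rate_floor, config.onset_run_length)
    # re-anchor the bin grid at onset so the baseline and response windows
    # fall on exact bin boundaries
    stim = bin_stimulus(smoothed, config.bin_width, anchor=onset)
    activity = bin_activity(rec.train, stim, config.bin_width)
    return stim, activity, onset


def _tt_branch(
    rec: Recording, stim, activity, onset: float, config: AnalysisConfig
) -> tuple[dict[str, TTFitResult], BaselineStats]:
    activity, baseline = normalize_nif(
        activity, onset, config.baseline_len
    )
    results: dict[str, TTFitResult] = {}
    for direction in ("cooling", "heating"):
        points = tt_mod.collect_points(
            activity,
            stim,
            baseline,
            onset,
            window=config.response_window,
            direction=direction,
            min_abs_rate=config.rate_floor_points,
        )
        if len(points) < 4:
            continue
        try:
            fit = tt_mod.fit_dose_response(points, config.qc_p, config.qc_r)
        except ValueError:
            continue
        smallest = _smallest_tested(points)
        fit = tt_mod.finalize_tt_fit(
            fit,
            baseline,
            gamma=config.gamma,
            phi_rounding=config.phi_rounding,
            smallest_tested=smallest,
        )
        results[direction] = fit
    return results, baseline


def _smallest_tested(points) -> float:
    """Smallest tested stimulus magnitude among the collected points."""
    return math.exp(min(p.log_rate for p in points))


def _st_branch(rec: Recording, stim, activity, config: AnalysisConfig) -> STFitResult:
    temps = np.array([b.mean_temp for b in stim])
    rates_by_start = {a.bin_start: a.mean_rate for a in activity}
    rates = np.array([rates_by_start.get(b.bin_start, np.nan) for b in stim])
    fit = st_mod.fit_sigmoid(temps, rates)
    if fit.converged:
        fit = st_mod.finalize_st_fit(
            temps,
            rates,
            fit,
            rule=config.working_range_rule,
            half_window=config.st_half_window,
            gamma=config.gamma,
            phi_rounding=config.phi_rounding,
        )
    return fit


def run_recording(rec: Recording, config: AnalysisConfig | None = None) -> RecordingResult:
    """Run the full per-recording analysis for the unit's neuron class.

    Class "TT" runs the flux dose-response branch, "ST" the sigmoid branch,
    "unknown" runs both and reports whatever passes QC. Stage failures are
    raised as :class:`StageError` carrying the unit id and stage name.
    """
    config = config or AnalysisConfig()
    result = RecordingResult(unit_id=rec.unit_id, neuron_class=rec.neuron_class)
    try:
        stim, activity, onset = _prepare(rec, config)
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise StageError(rec.unit_id, "prepare", exc) from exc

    run_tt = rec.neuron_class in ("TT", "unknown")
    run_st = rec.neuron_class in ("ST", "unknown")
    if run_tt:
        try:
            result.tt, result.baseline = _tt_branch(rec, stim, activity, onset, config)
        except Exception as exc:  # noqa: BLE001
            if rec.neuron_class == "TT":
                raise StageError(rec.unit_id, "tt_doseresponse", exc) from exc
            result.errors.append(f"tt_doseresponse: {exc}")
    if run_st:
        try:
            result.st = _st_branch(rec, stim, activity, config)
        except Exception as exc:  # noqa: BLE001
            if rec.neuron_class == "ST":
                raise StageError(rec.unit_id, "st_doseresponse", exc) from exc
            result.errors.append(f"st_doseresponse: {exc}")
    return result


def analyze_tt_unit(
    recordings: list[Recording],
    config: AnalysisConfig | None = None,
    direction: str = "cooling",
) -> tuple[TTFitResult, BaselineStats]:
    """Characterize one TT unit from several recordings at different ramp rates.

    Dose-response points are collected per recording (each normalized to its
    own pre-stimulus baseline) and pooled into a single regression; the
    noise level used for the detection threshold is the mean across the
    recordings' baselines.
    """
    config = config or AnalysisConfig()
    all_points = []
    baselines: list[BaselineStats] = []
    for rec in recordings:
        stim, activity, onset = _prepare(rec, config)
        activity, baseline = normalize_nif(activity, onset, config.baseline_len)
        baselines.append(baseline)
        all_points.extend(
            tt_mod.collect_points(
                activity,
                stim,
                baseline,
                onset,
                window=config.response_window,
                direction=direction,
                min_abs_rate=config.rate_floor_points,
            )
        )
    pooled = BaselineStats(
        window=(float("nan"), float("nan")),
        mean_nif=100.0,
        sd_nif=float(np.mean([b.sd_nif for b in baselines])),
        noise_level=float(np.mean([b.noise_level for b in baselines])),
        mean_rate_hz=float(np.mean([b.mean_rate_hz for b in baselines])),
        n_bins=int(sum(b.n_bins for b in baselines)),
    )
    fit = tt_mod.fit_dose_response(all_points, config.qc_p, config.qc_r)
    fit = tt_mod.finalize_tt_fit(
        fit,
        pooled,
        gamma=config.gamma,
        phi_rounding=config.phi_rounding,
        smallest_tested=_smallest_tested(all_points),
    )
    return fit, pooled


def analyze_cohort(
    recordings: list[Recording], config: AnalysisConfig | None = None
) -> list[RecordingResult]:
    """Run every recording; a failing unit is reported, never fatal."""
    config = config or AnalysisConfig()
    out: list[RecordingResult] = []
    for rec in recordings:
        try:
            out.append(run_recording(rec, config))
        except StageError as exc:
            log.warning("unit %s failed: %s", exc.unit_id, exc)
            out.append(
                RecordingResult(
                    unit_id=exc.unit_id,
                    neuron_class=rec.neuron_class,
                    errors=[f"{exc.stage}: {exc.cause}"],
                )
            )
    return out


# ---------------------------------------------------------------------------
# cohort summaries


def _flatten(result: RecordingResult) -> list[dict]:
    rows: list[dict] = []
    for direction, fit in result.tt.items():
        rows.append(
            {
                "unit_id": result.unit_id,
                "neuron_class": "TT",
                "direction": direction,
                "slope_decade": fit.slope_decade,
                "pearson_r": fit.pearson_r,
                "p_value": fit.p_value,
                "sigma": fit.residual_sd,
                "detection_threshold": fit.detection_threshold,
                "detection_threshold_abs": abs(fit.detection_threshold),
                "resolving_power": fit.resolving_power,
                "resting_rate_hz": result.baseline.mean_rate_hz
                if result.baseline
                else float("nan"),
                "noise_level": result.baseline.noise_level
                if result.baseline
                else float("nan"),
                "qc_pass": fit.qc_pass,
                "n_points": fit.n_points,
            }
        )
    if result.st is not None:
        f = result.st
        rows.append(
            {
                "unit_id": result.unit_id,
                "neuron_class": "ST",
                "rate_high": f.rate_high,
                "rate_low": f.rate_low,
                "midpoint_temp": f.midpoint_temp,
                "slope_at_midpoint": f.slope_at_midpoint,
                "working_low": f.working_low,
                "working_high": f.working_high,
                "resolving_power_c": f.resolving_power_c,
                "converged": f.converged,
            }
        )
    return rows


@dataclass
class CohortSummary:
    tables: dict[str, pd.DataFrame]
    summaries: dict[str, pd.DataFrame]
    correlations: pd.DataFrame
    comparisons: pd.DataFrame


_DEFAULT_PAIRS = (
    ("resting_rate_hz", "detection_threshold_abs"),
    ("detection_threshold_abs", "slope_decade"),
)


def _holm(pvals: list[float]) -> list[float]:
    """Holm step-down adjustment (reported alongside raw p-values)."""
    n = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(n)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (n - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def cohort_summary(
    results: list[RecordingResult],
    correlation_pairs=_DEFAULT_PAIRS,
    group_key: str | None = None,
    group_labels: dict[str, str] | None = None,
) -> CohortSummary:
    """Aggregate per-unit results into tables, stats, correlations, tests.

    Per neuron class: the parameter table, and per-parameter mean, SD,
    median, min, max, n. Pearson correlations (two-sided p) for the
    configured parameter pairs; a constant input makes the correlation
    not-computable and it is reported as NaN, never 1. Mann-Whitney U
    compares groups given by ``group_labels`` (unit_id -> label).
    Correlation and comparison p-values are exploratory and unadjusted; a
    Holm-adjusted column is emitted alongside for transparency.
    """
    rows = [row for res in results for row in _flatten(res)]
    if len(rows) < 2:
        raise ValueError("need >= 2 analyzable results to summarize")
    df = pd.DataFrame(rows)

    tables: dict[str, pd.DataFrame] = {}
    summaries: dict[str, pd.DataFrame] = {}
    for cls, sub in df.groupby("neuron_class"):
        sub = sub.dropna(axis=1, how="all")
        tables[cls] = sub.reset_index(drop=True)
        num = sub.select_dtypes(include=[float, int])
        stats_rows = []
        for col in num.columns:
            vals = num[col].dropna()
            if vals.empty:
                continue
            stats_rows.append(
                {
                    "parameter": col,
                    "mean": vals.mean(),
                    "sd": vals.std(ddof=1) if len(vals) > 1 else float("nan"),
                    "median": vals.median(),
                    "min": vals.min(),
                    "max": vals.max(),
                    "n": len(vals),
                }
            )
        summaries[cls] = pd.DataFrame(stats_rows)

    corr_rows = []
    tt = df[df["neuron_class"] == "TT"] if "TT" in set(df["neuron_class"]) else df.iloc[0:0]
    for xcol, ycol in correlation_pairs:
        if xcol not in tt.columns or ycol not in tt.columns:
            continue
        sub = tt[[xcol, ycol]].dropna()
        if len(sub) < 3 or sub[xcol].nunique() < 2 or sub[ycol].nunique() < 2:
            corr_rows.append(
                {"pair": f"{xcol}~{ycol}", "pearson_r": float("nan"),
                 "p_value": float("nan"), "n": len(sub),
                 "note": "not computable (constant or too few values)"}
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r, p = sstats.pearsonr(sub[xcol], sub[ycol])
        corr_rows.append(
            {"pair": f"{xcol}~{ycol}", "pearson_r": float(r), "p_value": float(p),
             "n": len(sub), "note": ""}
        )
    correlations = pd.DataFrame(corr_rows)
    if not correlations.empty:
        valid = correlations["p_value"].notna()
        adj = pd.Series(float("nan"), index=correlations.index)
        if valid.any():
            adj[valid] = _holm(correlations.loc[valid, "p_value"].tolist())
        correlations["p_holm"] = adj

    comp_rows = []
    if group_labels:
        key = group_key or "group"
        tt2 = df[df["neuron_class"] == "TT"].copy()
        tt2[key] = tt2["unit_id"].map(group_labels)
        groups = [g for g in tt2[key].dropna().unique()]
        if len(groups) == 2:
            for col in ("detection_threshold_abs", "slope_decade", "resolving_power"):
                if col not in tt2.columns:
                    continue
                a = tt2.loc[tt2[key] == groups[0], col].dropna()
                b = tt2.loc[tt2[key] == groups[1], col].dropna()
                if len(a) < 2 or len(b) < 2:
                    continue
                if len(a) == len(b) and np.allclose(np.sort(a), np.sort(b)):
                    u, p = float("nan"), 1.0
                else:
                    u, p = sstats.mannwhitneyu(a, b, alternative="two-sided")
                comp_rows.append(
                    {"parameter": col, "groups": f"{groups[0]} vs {groups[1]}",
                     "U": float(u), "p_value": float(p),
                     "n1": len(a), "n2": len(b)}
                )
    comparisons = pd.DataFrame(comp_rows)
    if not comparisons.empty:
        comparisons["p_holm"] = _holm(comparisons["p_value"].tolist())
    return CohortSummary(tables, summaries, correlations, comparisons)


# ---------------------------------------------------------------------------
# reports


def _result_to_dict(result: RecordingResult) -> dict:
    out: dict = {
        "unit_id": result.unit_id,
        "neuron_class": result.neuron_class,
        "errors": result.errors,
    }
    out["tt"] = {d: asdict(f) for d, f in result.tt.items()}
    out["st"] = asdict(result.st) if result.st is not None else None
    out["baseline"] = asdict(result.baseline) if result.baseline is not None else None
    return out


def write_report(
    results: list[RecordingResult],
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
    summary: CohortSummary | None = None,
    seeds: list[int] | None = None,
    plots: bool = False,
) -> dict[str, Path]:
    """Write per-unit JSON, cohort CSVs and a run manifest.

    Output is byte-identical across reruns with the same results and config
    (no timestamps; sorted JSON keys). With ``plots=True`` per-unit
    diagnostic figures are additionally rendered (excluded from the
    determinism contract).
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or AnalysisConfig()
    written: dict[str, Path] = {}

    for result in results:
        p = out_dir / f"{result.unit_id}.json"
        with open(p, "w") as fh:
            json.dump(_result_to_dict(result), fh, indent=2, sort_keys=True,
                      allow_nan=True)
            fh.write("\n")
        written[result.unit_id] = p

    rows = [row for res in results for row in _flatten(res)]
    cohort_path = out_dir / "cohort.csv"
    pd.DataFrame(rows).to_csv(cohort_path, index=False)
    written["cohort"] = cohort_path

    if summary is not None:
        for cls, tab in summary.summaries.items():
            p = out_dir / f"summary_{cls}.csv"
            tab.to_csv(p, index=False)
            written[f"summary_{cls}"] = p
        if not summary.correlations.empty:
            p = out_dir / "correlations.csv"
            summary.correlations.to_csv(p, index=False)
            written["correlations"] = p
        if not summary.comparisons.empty:
            p = out_dir / "comparisons.csv"
            summary.comparisons.to_csv(p, index=False)
            written["comparisons"] = p

    manifest = {
        "tool": "thermocode",
        "version": __version__,
        "config": asdict(config),
        "config_sha256": config.sha256(),
        "seeds": seeds or [],
        "n_units": len(results),
        "n_failed": sum(1 for r in results if r.errors and not r.tt and r.st is None),
    }
    mpath = out_dir / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written["manifest"] = mpath
    if not results:
        log.warning("no results: wrote manifest only")

    if plots:
        _write_plots(results, out_dir)
    return written


def _write_plots(results: list[RecordingResult], out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for result in results:
        for direction, fit in result.tt.items():
            fig, ax = plt.subplots(figsize=(5, 4))
            xs = np.linspace(-5, 0, 100)
            ax.plot(xs, fit.intercept + fit.slope_ln * xs, "k-", label="regression")
            ax.fill_between(
                xs,
                fit.intercept + fit.slope_ln * xs - fit.stim_noise_level,
                fit.intercept + fit.slope_ln * xs + fit.stim_noise_level,
                alpha=0.2,
                label="2$\\sigma$ band",
            )
            ax.set_xlabel("ln |temperature changing rate| (ln degC/s)")
            ax.set_ylabel("nIF (%)")
            ax.set_title(f"{result.unit_id} {direction}")
            ax.legend()
            fig.savefig(out_dir / f"{result.unit_id}_{direction}_doseresponse.png", dpi=100)
            plt.close(fig)
        if result.st is not None and result.st.converged:
            f = result.st
            fig, ax = plt.subplots(figsize=(5, 4))
            ts = np.linspace(f.midpoint_temp - 6, f.midpoint_temp + 6, 200)
            ax.plot(ts, st_mod.logistic(ts, f.rate_high, f.rate_low,
                                        f.midpoint_temp, f.width), "r-")
            for wv in (f.working_low, f.working_high):
                if np.isfinite(wv):
                    ax.axvline(wv, ls="--", color="gray")
            ax.set_xlabel("temperature (degC)")
            ax.set_ylabel("mean rate (APs/s)")
            ax.set_title(f"{result.unit_id} sigmoid fit")
            fig.savefig(out_dir / f"{result.unit_id}_sigmoid.png", dpi=100)
            plt.close(fig)
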