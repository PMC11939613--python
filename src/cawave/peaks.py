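"""Calcium-transient detection against baseline variability.

A transient (peak) is a maximal run of consecutive samples whose detrended
fluorescence strictly exceeds ``threshold_mult`` times the baseline noise
dispersion (default 3.5x the baseline SD), surviving a minimum-width
filter.  The slow-wave transients of interest are tens of seconds wide and
2-2.5x the baseline, so the detector's job is mostly calibration: the
baseline level and its noise SD must be estimated from recordings in which
a single transient can cover most of the 60 s window.

Baseline estimation is therefore robust on two axes:

* the slow trend (photobleaching) is taken as a rolling low-percentile of
  the trace (a global percentile when the window covers the whole
  recording), re-centred with the Gaussian quantile correction
  ``z = Phi^-1(1 - q/100)`` times the noise SD;
* the noise SD is a median-based estimate from first differences,
  ``sd = median(|diff|) / (sqrt(2) * 0.67449)``, which slow transients
  leave essentially untouched - so a peaking cell does not raise its own
  threshold.

``detect_peaks`` runs two passes: calls from the first-pass baseline are
used to re-centre the baseline on the median of out-of-transient samples
(calls padded by 25% of their width), and detection is repeated.  This
removes the percentile-centring bias when transients occupy most of the
recording.

The "wavelength" of a transient is reported as its threshold-crossing
width (the duration of one wave), not an oscillation period.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .roi import Trace

__all__ = [
    "DetectorConfig",
    "BaselineStats",
    "PeakCall",
    "CellSummary",
    "WellActivity",
    "PooledActivity",
    "estimate_baseline",
    "detect_peaks",
    "summarize_cell",
    "well_activity",
    "pooled_activity",
    "analyze_traces",
    "calls_to_frame",
]

# median(|N(0,1)|) scaling constant for MAD-type estimators
_MAD_SCALE = 0.6744897501960817


@dataclass(frozen=True)
class DetectorConfig:
    """Detection thresholds and baseline-estimation choices.

    threshold_mult: multiple of the baseline dispersion a sample must exceed
        (strictly) to belong to a transient; 3.5 by default.
    threshold_basis: 'sd' applies the multiple to the baseline SD (the
        standard dF criterion); 'variance' applies it to the SD squared for
        a literal x-times-the-variance threshold.
    min_width_s: minimum transient duration; rejects single-frame shot
        noise (target waves are ~40-50 s, so 2 s leaves a >10x margin).
    baseline_method: 'rolling_percentile' (default) or 'global_median'.
    rolling_window_s / rolling_percentile: trend window and percentile; a
        window covering the whole recording degenerates to a global
        percentile, appropriate for 1-min recordings where transients are
        wider than any usable sub-window.
    """

    threshold_mult: float = 3.5
    threshold_basis: str = "sd"
    min_width_s: float = 2.0
    baseline_method: str = "rolling_percentile"
    rolling_window_s: float = 60.0
    rolling_percentile: float = 10.0

    def __post_init__(self) -> None:
        if not self.threshold_mult > 0:
            raise ValueError(f"threshold_mult must be > 0, got {self.threshold_mult}")
        if self.threshold_basis not in ("sd", "variance"):
            raise ValueError(f"threshold_basis must be 'sd' or 'variance', got {self.threshold_basis!r}")
        if self.baseline_method not in ("rolling_percentile", "global_median"):
            raise ValueError(f"unknown baseline_method {self.baseline_method!r}")
        if not 0 < self.rolling_percentile < 100:
            raise ValueError("rolling_percentile must be in (0, 100)")
        if not self.min_width_s > 0:
            raise ValueError("min_width_s must be > 0")


@dataclass
class BaselineStats:
    """Baseline level and noise dispersion of one trace."""

    baseline_mean: float
    baseline_sd: float
    detrend_model: str
    trend: np.ndarray


@dataclass
class PeakCall:
    """One detected transient; frame indices are 0-based, half-open [onset, offset)."""

    onset_idx: int
    offset_idx: int
    peak_idx: int
    fold_amplitude: float
    width_s: float

    def __post_init__(self) -> None:
        if not self.onset_idx <= self.peak_idx < self.offset_idx:
            raise ValueError(f"peak_idx {self.peak_idx} outside run [{self.onset_idx}, {self.offset_idx})")
        if not self.width_s > 0:
            raise ValueError("width_s must be > 0")


@dataclass
class CellSummary:
    cell_id: str
    has_peak: bool
    n_peaks: int
    mean_fold: float | None
    mean_width_s: float | None


@dataclass
class WellActivity:
    well_id: str
    n_cells: int
    n_peaking: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_peaking <= self.n_cells:
            raise ValueError("need 0 <= n_peaking <= n_cells")

    @property
    def pct_peaking(self) -> float:
        return 100.0 * self.n_peaking / self.n_cells


@dataclass
class PooledActivity:
    """Cohort-level activity: percentage pooled over cells, plus the
    across-well mean +/- SD of per-well percentages."""

    n_wells: int
    n_cells: int
    n_peaking: int
    pct_peaking: float
    well_mean_pct: float
    well_sd_pct: float


# ---------------------------------------------------------------------------
# Baseline


def _noise_sd_from_diffs(residual: np.ndarray) -> float:
    d = np.diff(residual)
    return float(np.median(np.abs(d)) / (np.sqrt(2.0) * _MAD_SCALE))


def _raw_trend(x: np.ndarray, fps: float, cfg: DetectorConfig) -> tuple[np.ndarray, str]:
    n = x.size
    if cfg.baseline_method == "global_median":
        return np.full(n, np.median(x)), "global median"
    window = int(round(cfg.rolling_window_s * fps))
    if window > n:
        raise ValueError(f"trace of {n} frames is shorter than the {window}-frame rolling window")
    q = cfg.rolling_percentile / 100.0
    if window >= n:
        trend = np.full(n, np.quantile(x, q))
        desc = f"global {cfg.rolling_percentile:g}th percentile"
    else:
        trend = (
            pd.Series(x)
            .rolling(window, center=True, min_periods=max(2, window // 2))
            .quantile(q)
            .to_numpy()
        )
        # edges fall back to the nearest valid value
        valid = np.isfinite(trend)
        trend = np.interp(np.arange(n), np.flatnonzero(valid), trend[valid])
        desc = f"rolling {cfg.rolling_percentile:g}th percentile, {cfg.rolling_window_s:g} s window"
    return trend, desc


def estimate_baseline(trace: Trace, cfg: DetectorConfig = DetectorConfig()) -> BaselineStats:
    """Baseline trend, level, and noise SD of a trace.

    The returned ``trend`` is the slow baseline (bleaching) curve re-centred
    on the noise distribution; ``baseline_mean`` is its average level and
    ``baseline_sd`` the transient-insensitive noise SD.
    """
    x = trace.values
    trend_raw, desc = _raw_trend(x, trace.fps, cfg)
    sd = _noise_sd_from_diffs(x - trend_raw)
    if cfg.baseline_method == "global_median":
        z = 0.0
    else:
        z = stats.norm.ppf(1.0 - cfg.rolling_percentile / 100.0)
    trend = trend_raw + z * sd
    return BaselineStats(
        baseline_mean=float(np.mean(trend)),
        baseline_sd=sd,
        detrend_model=desc,
        trend=trend,
    )


# ---------------------------------------------------------------------------
# Detection


def _threshold(sd: float, cfg: DetectorConfig) -> float:
    return cfg.threshold_mult * (sd if cfg.threshold_basis == "sd" else sd**2)


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, stop) index pairs."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False])).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def _calls_from_baseline(
    x: np.ndarray, fps: float, trend: np.ndarray, center_level: float, sd: float, cfg: DetectorConfig
) -> list[PeakCall]:
    detrended = x - trend
    thr = _threshold(sd, cfg)
    runs = [
        (a, b)
        for a, b in _runs_above(detrended > thr)
        if (b - a) / fps >= cfg.min_width_s
    ]
    calls = []
    for a, b in runs:
        peak = a + int(np.argmax(x[a:b]))
        calls.append(
            PeakCall(
                onset_idx=a,
                offset_idx=b,
                peak_idx=peak,
                fold_amplitude=float(x[peak] / center_level) if center_level > 0 else float("nan"),
                width_s=(b - a) / fps,
            )
        )
    return calls


def detect_peaks(trace: Trace, cfg: DetectorConfig = DetectorConfig()) -> list[PeakCall]:
    """Detect transients as supra-threshold runs; two-pass baseline re-centring.

    Returns calls ordered by onset (an empty list is a valid result).
    ``fold_amplitude`` is the raw peak maximum over the baseline level.
    """
    x = trace.values
    bs = estimate_baseline(trace, cfg)
    if bs.baseline_sd == 0 and np.ptp(x - bs.trend) == 0:
        return []  # constant (degenerate) trace: no excursions, undefined noise scale
    calls = _calls_from_baseline(x, trace.fps, bs.trend, bs.baseline_mean, bs.baseline_sd, cfg)

    # second pass: refit the slow baseline on out-of-transient samples
    # (calls padded by 5% of their width to drop sub-threshold tails).
    # When the remaining samples span the recording, a linear fit captures
    # the bleaching decay; when a wide transient leaves baseline only at
    # one end, a constant (median) level avoids unstable extrapolation.
    # Either way this removes the low-percentile centring bias that a
    # single-pass estimate suffers when transients cover most of the trace.
    t = np.arange(x.size) / trace.fps
    keep = np.ones(x.size, dtype=bool)
    for call in calls:
        pad = max(2, int(round(0.05 * (call.offset_idx - call.onset_idx))))
        keep[max(0, call.onset_idx - pad) : min(x.size, call.offset_idx + pad)] = False
    n_keep = int(keep.sum())
    if n_keep < 10:
        return calls
    if n_keep >= 20 and np.ptp(t[keep]) >= 0.5 * t[-1]:
        coef = np.polyfit(t[keep], x[keep], 1)
        trend = np.polyval(coef, t)
    else:
        trend = np.full(x.size, float(np.median(x[keep])))
    center = float(np.mean(trend))
    return _calls_from_baseline(x, trace.fps, trend, center, bs.baseline_sd, cfg)


def summarize_cell(trace: Trace, calls: Sequence[PeakCall]) -> CellSummary:
    """Per-cell aggregate of the detector output."""
    n = len(calls)
    return CellSummary(
        cell_id=trace.cell_id,
        has_peak=n >= 1,
        n_peaks=n,
        mean_fold=float(np.mean([c.fold_amplitude for c in calls])) if n else None,
        mean_width_s=float(np.mean([c.width_s for c in calls])) if n else None,
    )


def well_activity(summaries: Sequence[CellSummary], well_id: str = "well") -> WellActivity:
    """Fraction of cells in one well with at least one detected transient."""
    if not summaries:
        raise ValueError("well_activity requires at least one cell summary")
    return WellActivity(
        well_id=well_id,
        n_cells=len(summaries),
        n_peaking=sum(s.has_peak for s in summaries),
    )


def pooled_activity(wells: Sequence[WellActivity]) -> PooledActivity:
    """Pool cells across wells; also report the across-well mean +/- SD."""
    if not wells:
        raise ValueError("pooled_activity requires at least one well")
    n_cells = sum(w.n_cells for w in wells)
    n_peaking = sum(w.n_peaking for w in wells)
    pcts = np.array([w.pct_peaking for w in wells])
    return PooledActivity(
        n_wells=len(wells),
        n_cells=n_cells,
        n_peaking=n_peaking,
        pct_peaking=100.0 * n_peaking / n_cells,
        well_mean_pct=float(pcts.mean()),
        well_sd_pct=float(pcts.std(ddof=1)) if len(wells) > 1 else 0.0,
    )


def _well_of(cell_id: str) -> str:
    return cell_id.split(":", 1)[0] if ":" in cell_id else "well"


def analyze_traces(
    traces: Iterable[Trace], cfg: DetectorConfig = DetectorConfig()
) -> tuple[list[CellSummary], list[WellActivity], PooledActivity]:
    """Detect peaks on every trace and aggregate per well and cohort-wide.

    Cells are grouped into wells by the ``well:cell`` identifier convention;
    identifiers without a colon all fall into a single well.
    """
    summaries: list[CellSummary] = []
    by_well: dict[str, list[CellSummary]] = defaultdict(list)
    for tr in traces:
        s = summarize_cell(tr, detect_peaks(tr, cfg))
        summaries.append(s)
        by_well[_well_of(tr.cell_id)].append(s)
    wells = [well_activity(group, well_id) for well_id, group in by_well.items()]
    return summaries, wells, pooled_activity(wells)


def calls_to_frame(calls_by_cell: dict[str, Sequence[PeakCall]], fps: float) -> pd.DataFrame:
    """Flatten per-cell calls to a table (onset/offset/peak in seconds)."""
    rows = []
    for cell_id, calls in calls_by_cell.items():
        for c in calls:
            rows.append(
                {
                    "cell_id": cell_id,
                    "onset_s": c.onset_idx / fps,
                    "offset_s": c.offset_idx / fps,
                    "peak_s": c.peak_idx / fps,
                    "fold": c.fold_amplitude,
                    "width_s": c.width_s,
                }
            )
    return pd.DataFrame(rows, columns=["cell_id", "onset_s", "offset_s", "peak_s", "fold", "width_s"])
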