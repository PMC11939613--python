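"""Synthetic calcium recordings, image stacks, and viability plates.

The generator emulates the statistical structure of a slow-wave calcium
imaging screen: 1-min recordings at 15 frames/s in which a fraction of
cells exhibit broad (tens of seconds) fluorescence transients of 2-2.5x
the baseline, riding on a noisy and optionally photobleaching baseline;
drug-effect transforms of those recordings (complete / partial / transient
suppression); and plate-reader viability tables whose dose-normalized means
follow a four-parameter logistic truth with multiplicative replicate noise
and vehicle-control (DMSO) wells.

Every generated object carries its ground truth alongside, so downstream
detection and fitting can be tested as parameter-recovery problems without
any external data.  All randomness is driven by explicit integer seeds and
is bitwise-reproducible.

Transient shape
---------------
Transients are half-sine bumps: for an event centred at ``c`` with width
``w`` the added fluorescence at time ``t in [c-w/2, c+w/2]`` is
``f0*(peak_fold-1)*sin(pi*(t-(c-w/2))/w)``, so the peak maximum is exactly
``f0*peak_fold`` (before bleaching/noise).  The half-sine rises steeply
from zero, so its width measured at a low detection threshold is close to
the nominal width ``w`` - the property the width-recovery analysis relies
on.  Events are placed by a Poisson process thinned to forbid overlap,
with the event count zero-truncated for cells labelled as peaking (a
"peaking" cell is one that shows at least one transient in the recording
window, matching how the phenotype is scored).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .roi import Roi, Trace

__all__ = [
    "TraceGenParams",
    "CohortGenParams",
    "DrugEffectSpec",
    "PlateGenParams",
    "StackGeometry",
    "SyntheticStack",
    "CellRecording",
    "WellRecordingSet",
    "trace_model",
    "generate_trace",
    "generate_cohort",
    "apply_drug_effect",
    "generate_image_stack",
    "four_pl",
    "generate_viability_plate",
    "generate_viability_plate_from_profile",
]

DRUG_MODES = ("none", "complete", "partial", "rebound")


@dataclass(frozen=True)
class TraceGenParams:
    """Generative parameters for a single-cell fluorescence trace.

    Defaults encode the study conditions: 60 s recordings at 15 fps,
    baseline 100 a.u. with additive noise SD 3, mild photobleaching
    (5%/min multiplicative linear decay), and 2.5-fold transients of
    40 s nominal width at about one event per minute.
    """

    duration_s: float = 60.0
    fps: float = 15.0
    baseline_f0: float = 100.0
    noise_sd: float = 3.0
    bleach_frac_per_min: float = 0.05
    peak_fold: float = 2.5
    peak_width_s: float = 40.0
    peaks_per_min: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.baseline_f0 > 0:
            raise ValueError(f"baseline_f0 must be > 0, got {self.baseline_f0}")
        if not self.fps > 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")
        if not self.peak_width_s > 0:
            raise ValueError(f"peak_width_s must be > 0, got {self.peak_width_s}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0 <= self.bleach_frac_per_min < 1:
            raise ValueError(f"bleach_frac_per_min must be in [0, 1), got {self.bleach_frac_per_min}")
        if self.peak_fold < 1:
            raise ValueError(f"peak_fold must be >= 1, got {self.peak_fold}")
        if self.peaks_per_min < 0:
            raise ValueError(f"peaks_per_min must be >= 0, got {self.peaks_per_min}")
        n = self.duration_s * self.fps
        if abs(n - round(n)) > 1e-9 or round(n) < 2:
            raise ValueError(f"duration_s*fps must be an integer >= 2, got {n}")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass(frozen=True)
class CohortGenParams:
    """A cohort of wells, each well holding ``cells_per_well`` recorded cells."""

    n_wells: int = 44
    cells_per_well: int = 10
    p_peaking: float = 0.67
    trace_params: TraceGenParams = field(default_factory=TraceGenParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wells < 1 or self.cells_per_well < 1:
            raise ValueError("n_wells and cells_per_well must be >= 1")
        if not 0 <= self.p_peaking <= 1:
            raise ValueError(f"p_peaking must be in [0, 1], got {self.p_peaking}")


@dataclass(frozen=True)
class DrugEffectSpec:
    """How a drug transforms the peaking phenotype post-treatment.

    mode 'none'      -- post-treatment recordings identical in law to baseline;
    mode 'complete'  -- every cell loses all transients at every timepoint;
    mode 'partial'   -- each peaking cell keeps its activity with prob. p_retain;
    mode 'rebound'   -- all activity suppressed before ``rebound_at_min``,
                        restored at and after it.
    """

    mode: str = "none"
    p_retain: float = 0.5
    rebound_at_min: float = 30.0
    timepoints_min: tuple[float, ...] = (1.0, 20.0, 40.0)

    def __post_init__(self) -> None:
        if self.mode not in DRUG_MODES:
            raise ValueError(f"unknown drug-effect mode {self.mode!r}; expected one of {DRUG_MODES}")
        if not 0 <= self.p_retain <= 1:
            raise ValueError(f"p_retain must be in [0, 1], got {self.p_retain}")
        if not self.timepoints_min:
            raise ValueError("timepoints_min must be non-empty")


@dataclass(frozen=True)
class PlateGenParams:
    """One drug's dose-response plate: dose wells plus DMSO vehicle controls.

    ``four_pl_truth`` is (top_pct, bottom_pct, ic50_um, hill): the viability
    (% of control) that the normalized dose means follow.  ``noise_cv`` is
    the coefficient of variation of the multiplicative (lognormal, mean-1)
    replicate noise on raw fluorescence.
    """

    doses_um: tuple[float, ...] = (0.1, 0.5, 1.0, 5.0, 10.0, 25.0, 50.0)
    replicates: int = 3
    four_pl_truth: tuple[float, float, float, float] = (100.0, 5.0, 10.0, 1.0)
    noise_cv: float = 0.10
    n_control_wells: int = 6
    control_mean_raw: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        d = np.asarray(self.doses_um, dtype=float)
        if d.size < 2 or np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise ValueError("doses_um must be >=2 strictly positive, strictly increasing values")
        top, bottom, ic50, _hill = self.four_pl_truth
        if not top > bottom or bottom < 0:
            raise ValueError("four_pl_truth requires top_pct > bottom_pct >= 0")
        if not ic50 > 0:
            raise ValueError("four_pl_truth ic50_um must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.replicates < 1 or self.n_control_wells < 1:
            raise ValueError("replicates and n_control_wells must be >= 1")
        if not self.control_mean_raw > 0:
            raise ValueError("control_mean_raw must be > 0")


@dataclass(frozen=True)
class StackGeometry:
    """Rendering geometry for a synthetic image stack."""

    frame_shape: tuple[int, int] = (128, 128)
    radius_px: tuple[float, float] = (4.0, 7.0)
    min_separation_px: float = 3.0
    background: float = 20.0
    pixel_noise_sd: float = 0.0
    max_placement_tries: int = 2000


@dataclass
class SyntheticStack:
    """A rendered image stack with its ROI and per-cell trace ground truth."""

    frames: np.ndarray
    roi_truth: list[Roi]
    per_cell_truth: list[Trace]


@dataclass
class CellRecording:
    well_id: str
    cell_id: str
    peaking: bool
    values: np.ndarray

    @property
    def label(self) -> str:
        return f"{self.well_id}:{self.cell_id}"


@dataclass
class WellRecordingSet:
    """All recorded cells of a cohort, with ground-truth peaking labels."""

    fps: float
    cells: list[CellRecording]
    trace_params: TraceGenParams | None = None

    def wells(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.cells:
            seen.setdefault(c.well_id)
        return list(seen)

    def truth_fraction(self) -> float:
        return float(np.mean([c.peaking for c in self.cells]))

    def to_traces(self) -> list[Trace]:
        return [Trace(cell_id=c.label, fps=self.fps, values=c.values) for c in self.cells]


# ---------------------------------------------------------------------------
# Trace generation


def trace_model(params: TraceGenParams, event_centers: Sequence[float], t: np.ndarray) -> np.ndarray:
    """Noise-free analytic trace: bleaching baseline plus half-sine bumps."""
    t = np.asarray(t, dtype=float)
    base = params.baseline_f0 * (1.0 - params.bleach_frac_per_min * t / 60.0)
    out = base.copy()
    amp = params.baseline_f0 * (params.peak_fold - 1.0)
    w = params.peak_width_s
    for c in event_centers:
        start = c - w / 2.0
        mask = (t >= start) & (t <= start + w)
        out[mask] += amp * np.sin(np.pi * (t[mask] - start) / w)
    return out


def draw_event_centers(params: TraceGenParams, rng: np.random.Generator) -> list[float]:
    """Event centres for a peaking cell: zero-truncated Poisson count at
    ``peaks_per_min``, placed uniformly with full support inside the
    recording, thinned to forbid overlap (bounded retries)."""
    if params.peak_width_s > params.duration_s:
        raise ValueError(
            f"peak_width_s={params.peak_width_s} does not fit inside duration_s={params.duration_s}"
        )
    mu = params.peaks_per_min * params.duration_s / 60.0
    n_target = max(1, int(rng.poisson(mu)))
    lo = params.peak_width_s / 2.0
    hi = params.duration_s - params.peak_width_s / 2.0
    centers: list[float] = []
    for _ in range(n_target):
        for _try in range(50):
            c = float(rng.uniform(lo, hi)) if hi > lo else lo
            if all(abs(c - c0) >= params.peak_width_s for c0 in centers):
                centers.append(c)
                break
        # event dropped if no non-overlapping slot found
    return sorted(centers)


def generate_trace(
    params: TraceGenParams,
    peaking: bool,
    rng: np.random.Generator | None = None,
) -> Trace:
    """One cell's recording; event placement and noise drawn from ``rng``
    (or a fresh generator seeded with ``params.seed``)."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    t = np.arange(params.n_frames) / params.fps
    centers = draw_event_centers(params, rng) if peaking else []
    values = trace_model(params, centers, t)
    if params.noise_sd > 0:
        values = values + rng.normal(0.0, params.noise_sd, size=t.size)
    return Trace(cell_id="cell", fps=params.fps, values=values)


def generate_cohort(params: CohortGenParams) -> WellRecordingSet:
    """n_wells x cells_per_well recordings with i.i.d. Bernoulli(p_peaking)
    ground-truth labels."""
    rng = np.random.default_rng(params.seed)
    cells: list[CellRecording] = []
    for w in range(params.n_wells):
        well_id = f"W{w + 1:03d}"
        for c in range(params.cells_per_well):
            peaking = bool(rng.random() < params.p_peaking)
            tr = generate_trace(params.trace_params, peaking, rng)
            cells.append(
                CellRecording(well_id=well_id, cell_id=f"c{c + 1:02d}", peaking=peaking, values=tr.values)
            )
    return WellRecordingSet(fps=params.trace_params.fps, cells=cells, trace_params=params.trace_params)


def apply_drug_effect(
    rec: WellRecordingSet,
    spec: DrugEffectSpec,
    seed: int = 0,
) -> dict[float, WellRecordingSet]:
    """Post-treatment recordings per timepoint, as fresh noise realizations
    of the same cells (identity preserved via well/cell ids).

    The per-cell retain decision in 'partial' mode is drawn once and applied
    at every timepoint (a cell either keeps or loses its activity).
    """
    if rec.trace_params is None:
        raise ValueError("recording set lacks trace_params; cannot regenerate post-treatment traces")
    rng = np.random.default_rng(seed)
    retained = {c.label: bool(rng.random() < spec.p_retain) for c in rec.cells}
    out: dict[float, WellRecordingSet] = {}
    for tp in spec.timepoints_min:
        cells: list[CellRecording] = []
        for c in rec.cells:
            if spec.mode == "none":
                post_peaking = c.peaking
            elif spec.mode == "complete":
                post_peaking = False
            elif spec.mode == "partial":
                post_peaking = c.peaking and retained[c.label]
            elif spec.mode == "rebound":
                post_peaking = c.peaking and tp >= spec.rebound_at_min
            else:  # pragma: no cover - guarded by DrugEffectSpec
                raise ValueError(f"unknown mode {spec.mode!r}")
            tr = generate_trace(rec.trace_params, post_peaking, rng)
            cells.append(
                CellRecording(well_id=c.well_id, cell_id=c.cell_id, peaking=post_peaking, values=tr.values)
            )
        out[tp] = WellRecordingSet(fps=rec.fps, cells=cells, trace_params=rec.trace_params)
    return out


# ---------------------------------------------------------------------------
# Image stacks


def generate_image_stack(
    params: CohortGenParams,
    geometry: StackGeometry = StackGeometry(),
) -> SyntheticStack:
    """Render one well (``cells_per_well`` cells) as a time-lapse stack.

    Each cell is a disk whose pixel intensity in frame ``t`` equals its
    ground-truth trace value at ``t``; the background is a dark constant.
    Additive pixel noise (``geometry.pixel_noise_sd``) is applied to every
    pixel, so with zero pixel noise the ROI mean reproduces the truth trace
    exactly. Disk placement is rejection-sampled to keep full disks inside
    the frame and separated by ``min_separation_px``; an infeasible packing
    raises after ``max_placement_tries`` attempts.
    """
    rng = np.random.default_rng(params.seed)
    nrows, ncols = geometry.frame_shape
    rois: list[Roi] = []
    for i in range(params.cells_per_well):
        placed = False
        for _try in range(geometry.max_placement_tries):
            r = float(rng.uniform(*geometry.radius_px))
            cx = float(rng.uniform(r, ncols - 1 - r))
            cy = float(rng.uniform(r, nrows - 1 - r))
            ok = all(
                np.hypot(cx - q.center_x, cy - q.center_y) >= r + q.radius + geometry.min_separation_px
                for q in rois
            )
            if ok:
                rois.append(Roi(roi_id=f"roi{i + 1:02d}", center_x=cx, center_y=cy, radius=r))
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place {params.cells_per_well} non-overlapping cells in a "
                f"{geometry.frame_shape} frame after {geometry.max_placement_tries} tries"
            )

    tp = params.trace_params
    traces: list[Trace] = []
    for roi in rois:
        peaking = bool(rng.random() < params.p_peaking)
        tr = generate_trace(tp, peaking, rng)
        traces.append(Trace(cell_id=roi.roi_id, fps=tp.fps, values=tr.values))

    frames = np.full((tp.n_frames, nrows, ncols), geometry.background, dtype=float)
    from .roi import disk_mask

    for roi, tr in zip(rois, traces):
        mask = disk_mask((nrows, ncols), roi)
        frames[:, mask] = tr.values[:, None]
    if geometry.pixel_noise_sd > 0:
        frames = frames + rng.normal(0.0, geometry.pixel_noise_sd, size=frames.shape)
    return SyntheticStack(frames=frames, roi_truth=rois, per_cell_truth=traces)


# ---------------------------------------------------------------------------
# Viability plates


def four_pl(dose: np.ndarray, top: float, bottom: float, ic50: float, hill: float) -> np.ndarray:
    """Four-parameter logistic viability: bottom + (top-bottom)/(1+(d/IC50)^h)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative mean-1 lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def _assemble_plate(
    drug: str,
    doses: np.ndarray,
    mean_viability_pct: np.ndarray,
    replicates: int,
    noise_cv: float,
    n_control_wells: int,
    control_mean_raw: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows = []
    for j in range(n_control_wells):
        raw = control_mean_raw * _lognormal_factors(rng, noise_cv, 1)[0]
        rows.append(("CTRL%02d" % (j + 1), "DMSO", 0.0, raw))
    for i, (d, v) in enumerate(zip(doses, mean_viability_pct)):
        factors = _lognormal_factors(rng, noise_cv, replicates)
        for j in range(replicates):
            raw = control_mean_raw * (v / 100.0) * factors[j]
            rows.append((f"D{i + 1:02d}R{j + 1:02d}", drug, float(d), raw))
    return pd.DataFrame(rows, columns=["well", "condition", "dose_um", "raw_fluorescence"])


def generate_viability_plate(params: PlateGenParams, drug: str = "DRUG") -> pd.DataFrame:
    """Raw-fluorescence plate table whose DMSO-normalized dose means follow
    the 4PL truth. Columns: well, condition, dose_um, raw_fluorescence;
    control rows carry condition 'DMSO' and dose 0."""
    rng = np.random.default_rng(params.seed)
    doses = np.asarray(params.doses_um, dtype=float)
    truth = four_pl(doses, *params.four_pl_truth)
    return _assemble_plate(
        drug, doses, truth, params.replicates, params.noise_cv, params.n_control_wells,
        params.control_mean_raw, rng,
    )


def generate_viability_plate_from_profile(
    doses_um: Sequence[float],
    mean_viability_pct: Sequence[float],
    replicates: int = 5,
    noise_cv: float = 0.10,
    n_control_wells: int = 6,
    control_mean_raw: float = 1000.0,
    seed: int = 0,
    drug: str = "DRUG",
) -> pd.DataFrame:
    """Plate table from an arbitrary dose -> mean-viability profile.

    Covers response shapes outside the 4PL family (flat plates, non-monotone
    responses that rebound at high dose) used to exercise the IC50 quality
    gates.
    """
    doses = np.asarray(doses_um, dtype=float)
    profile = np.asarray(mean_viability_pct, dtype=float)
    if doses.shape != profile.shape:
        raise ValueError("doses_um and mean_viability_pct must have equal length")
    if np.any(doses <= 0) or np.any(np.diff(doses) <= 0):
        raise ValueError("doses_um must be strictly positive and strictly increasing")
    if np.any(profile < 0):
        raise ValueError("mean_viability_pct must be >= 0")
    rng = np.random.default_rng(seed)
    return _assemble_plate(drug, doses, profile, replicates, noise_cv, n_control_wells, control_mean_raw, rng)
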