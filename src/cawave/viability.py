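"""Viability normalization, four-parameter logistic fitting, and IC50 verdicts.

Plate-reader live-stain fluorescence is normalized to the mean of vehicle
(DMSO) control wells and expressed as percent viability.  Dose-response
curves are fitted with the four-parameter logistic

    V(d) = bottom + (top - bottom) / (1 + (d / IC50)^h)

by nonlinear least squares on log10(dose) (doses are serial dilutions, so
the natural axis is logarithmic).  IC50 is parameterized as log10(IC50),
keeping it positive; the Hill slope h is unconstrained in sign.  Fits use
multi-start initial values over an IC50 grid spanning the observed dose
range to avoid local minima.  Replicates enter as individual points, which
preserves the error structure for the case-resampling bootstrap CI.

An IC50 is only reported when all quality gates pass; otherwise the
verdict is "n/a" (no interpretable half-maximal dose), covering flat
plates, responses without a clear dose dependence, and fits extrapolating
far outside the tested range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synth import four_pl

__all__ = [
    "DoseResponseTable",
    "DoseResponseFit",
    "VerdictGates",
    "normalize_viability",
    "fit_4pl",
    "ic50_or_na",
    "max_cell_kill",
]

PLATE_COLUMNS = ("well", "condition", "dose_um", "raw_fluorescence")
CONTROL_CONDITION = "DMSO"


@dataclass
class DoseResponseTable:
    """Replicate viability (% of control) per dose for one drug."""

    drug: str
    data: pd.DataFrame  # columns: dose_um, viability_pct (one row per replicate)
    control_n: int
    control_cv: float

    def __post_init__(self) -> None:
        need = {"dose_um", "viability_pct"}
        if not need.issubset(self.data.columns):
            raise ValueError(f"dose-response table needs columns {sorted(need)}")
        d = self.data["dose_um"].to_numpy(dtype=float)
        v = self.data["viability_pct"].to_numpy(dtype=float)
        if np.any(d <= 0):
            raise ValueError("doses must be strictly positive")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("viability values must be finite and >= 0")

    @property
    def doses(self) -> np.ndarray:
        return np.unique(self.data["dose_um"].to_numpy(dtype=float))

    def dose_means(self) -> pd.Series:
        return self.data.groupby("dose_um")["viability_pct"].mean()


@dataclass(frozen=True)
class VerdictGates:
    """Quality gates deciding whether a fitted IC50 is reportable."""

    range_factor: float = 10.0  # IC50 must lie in tested range x [1/f, f]
    min_dynamic_range: float = 20.0  # top - bottom, percentage points
    max_spearman: float = -0.5  # mean viability vs dose must be this anti-monotone


@dataclass
class DoseResponseFit:
    """4PL fit results, quality verdict, and maximum observed cell-kill."""

    drug: str
    top_pct: float
    bottom_pct: float
    ic50_um: float
    hill: float
    converged: bool
    r_squared: float
    ic50_ci: tuple[float, float]
    verdict: str  # 'ic50' or 'n/a'
    max_kill_pct: float
    dose_range: tuple[float, float]
    dose_spearman: float
    sse: float


def normalize_viability(
    plate: pd.DataFrame,
    drug: str | None = None,
    control_condition: str = CONTROL_CONDITION,
) -> DoseResponseTable:
    """Express dose-well fluorescence as percent of the control-well mean.

    ``plate`` follows the plate-table schema (well, condition, dose_um,
    raw_fluorescence) with control rows under ``control_condition`` at dose
    0. With several drugs on one plate, ``drug`` selects which to extract.
    """
    missing = set(PLATE_COLUMNS) - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns {sorted(missing)}")
    controls = plate.loc[plate["condition"] == control_condition, "raw_fluorescence"]
    if controls.empty:
        raise ValueError(f"no {control_condition!r} control wells on plate")
    cmean = float(controls.mean())
    if cmean <= 0:
        raise ValueError(f"control mean must be positive, got {cmean}")
    drugs = sorted(set(plate["condition"]) - {control_condition})
    if drug is None:
        if len(drugs) != 1:
            raise ValueError(f"plate holds drugs {drugs}; specify which to normalize")
        drug = drugs[0]
    elif drug not in drugs:
        raise ValueError(f"drug {drug!r} not on plate (found {drugs})")
    sub = plate[plate["condition"] == drug]
    data = pd.DataFrame(
        {
            "dose_um": sub["dose_um"].to_numpy(dtype=float),
            "viability_pct": 100.0 * sub["raw_fluorescence"].to_numpy(dtype=float) / cmean,
        }
    ).sort_values("dose_um", kind="stable", ignore_index=True)
    return DoseResponseTable(
        drug=drug,
        data=data,
        control_n=len(controls),
        control_cv=float(controls.std(ddof=1) / cmean) if len(controls) > 1 else 0.0,
    )


def _grid_starts(
    logd: np.ndarray, y: np.ndarray, bounds: tuple, top_fixed: float | None, n_keep: int = 3
) -> list[np.ndarray]:
    """Multi-start seeds from a coarse (log IC50, hill) grid.

    For fixed (IC50, hill) the 4PL is linear in (top, bottom), so each grid
    point is scored by a closed-form least-squares solve; the best few are
    polished by the nonlinear optimizer.
    """
    lo, hi = bounds
    lg_grid = np.linspace(logd.min() - 1.0, logd.max() + 1.0, 15)
    hill_grid = np.array([-3.0, -1.0, 0.5, 1.0, 2.0, 4.0])
    scored: list[tuple[float, np.ndarray]] = []
    for lg in lg_grid:
        for h in hill_grid:
            s = 1.0 / (1.0 + 10.0 ** ((logd - lg) * h))
            if top_fixed is None:
                a = np.column_stack([s, 1.0 - s])
                coef, *_ = np.linalg.lstsq(a, y, rcond=None)
                top, bottom = float(coef[0]), float(coef[1])
            else:
                top = top_fixed
                bottom = float(np.sum((y - top * s) * (1.0 - s)) / max(np.sum((1.0 - s) ** 2), 1e-12))
            x0 = np.clip(np.array([top, bottom, lg, h]), lo + 1e-9, hi - 1e-9)
            pred = x0[1] + (x0[0] - x0[1]) * s
            scored.append((float(np.sum((pred - y) ** 2)), x0))
    scored.sort(key=lambda t: t[0])
    return [p for _, p in scored[:n_keep]]


def _fit_once(
    logd: np.ndarray, y: np.ndarray, x0: np.ndarray, bounds: tuple
) -> tuple[np.ndarray, float, bool]:
    def resid(p):
        top, bottom, log_ic50, hill = p
        return four_pl(10.0**logd, top, bottom, 10.0**log_ic50, hill) - y

    try:
        res = optimize.least_squares(resid, x0, bounds=bounds, method="trf", max_nfev=2000)
    except Exception:
        return x0, np.inf, False
    return res.x, float(np.sum(res.fun**2)), bool(res.success)


def fit_4pl(
    table: DoseResponseTable,
    seed: int = 0,
    n_boot: int = 500,
    gates: VerdictGates = VerdictGates(),
    top_fixed: float | None = None,
) -> DoseResponseFit:
    """Multi-start 4PL least squares on log-dose, with bootstrap IC50 CI.

    Requires >=4 distinct doses. Non-convergence is reported through
    ``converged`` (and an 'n/a' verdict), not raised. ``top_fixed`` pins the
    upper plateau (three-parameter variant). Deterministic under ``seed``.
    """
    doses = table.doses
    if doses.size < 4:
        raise ValueError(f"4PL fit needs >=4 distinct doses, got {doses.size}")
    d = table.data["dose_um"].to_numpy(dtype=float)
    y = table.data["viability_pct"].to_numpy(dtype=float)
    logd = np.log10(d)
    dmin, dmax = float(doses.min()), float(doses.max())

    if top_fixed is None:
        top_lo, top_hi = 0.0, max(300.0, 2 * y.max())
    else:
        top_lo, top_hi = top_fixed - 1e-9, top_fixed + 1e-9
    bounds = (
        np.array([top_lo, 0.0, np.log10(dmin) - 3.0, -10.0]),
        np.array([top_hi, max(200.0, y.max()), np.log10(dmax) + 3.0, 10.0]),
    )
    starts = _grid_starts(logd, y, bounds, top_fixed)
    best_p, best_sse, best_ok = None, np.inf, False
    for x0 in starts:
        p, sse, ok = _fit_once(logd, y, x0, bounds)
        if sse < best_sse:
            best_p, best_sse, best_ok = p, sse, ok
    assert best_p is not None
    top, bottom, log_ic50, hill = (float(v) for v in best_p)
    if top < bottom and top_fixed is None:
        # 4PL mirror symmetry: (top, bottom, h) and (bottom, top, -h) give
        # identical curves; report the canonical orientation.
        top, bottom, hill = bottom, top, -hill
    ic50 = 10.0**log_ic50
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - best_sse / tss if tss > 0 else float("nan")

    # case-resampling bootstrap over wells (replicate rows)
    rng = np.random.default_rng(seed)
    boot: list[float] = []
    n = y.size
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if np.unique(d[idx]).size < 4:
            continue
        p, _sse, ok = _fit_once(logd[idx], y[idx], best_p, bounds)
        if ok:
            boot.append(10.0 ** float(p[2]))
    if len(boot) >= 20:
        ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    else:
        ci = (float("nan"), float("nan"))

    means = table.dose_means()
    rho = stats.spearmanr(means.index.to_numpy(), means.to_numpy()).statistic
    fit = DoseResponseFit(
        drug=table.drug,
        top_pct=top,
        bottom_pct=bottom,
        ic50_um=ic50,
        hill=hill,
        converged=best_ok,
        r_squared=r2,
        ic50_ci=ci,
        verdict="pending",
        max_kill_pct=max_cell_kill(table),
        dose_range=(dmin, dmax),
        dose_spearman=float(rho) if np.isfinite(rho) else float("nan"),
        sse=best_sse,
    )
    fit.verdict = ic50_or_na(fit, gates)
    return fit


def ic50_or_na(fit: DoseResponseFit, gates: VerdictGates = VerdictGates()) -> str:
    """'ic50' when every quality gate passes, else 'n/a'.

    Gates: the optimizer converged; the fitted IC50 lies within the tested
    dose range widened by ``range_factor``; the fitted dynamic range
    (top - bottom) reaches ``min_dynamic_range`` points; and mean viability
    decreases with dose (Spearman rho <= ``max_spearman``).
    """
    dmin, dmax = fit.dose_range
    if not fit.converged:
        return "n/a"
    if not dmin / gates.range_factor <= fit.ic50_um <= dmax * gates.range_factor:
        return "n/a"
    if fit.top_pct - fit.bottom_pct < gates.min_dynamic_range:
        return "n/a"
    if not np.isfinite(fit.dose_spearman) or fit.dose_spearman > gates.max_spearman:
        return "n/a"
    return "ic50"


def max_cell_kill(table: DoseResponseTable) -> float:
    """100 minus the minimum over doses of mean replicate viability, in
    [0, 100]."""
    if table.data.empty:
        raise ValueError("empty dose-response table")
    kill = 100.0 - float(table.dose_means().min())
    return float(np.clip(kill, 0.0, 100.0))


def fits_to_frame(fits: Sequence[DoseResponseFit]) -> pd.DataFrame:
    rows = []
    for f in fits:
        rows.append(
            {
                "drug": f.drug,
                "top_pct": f.top_pct,
                "bottom_pct": f.bottom_pct,
                "ic50_um": f.ic50_um if f.verdict == "ic50" else np.nan,
                "hill": f.hill,
                "r_squared": f.r_squared,
                "ic50_ci_lo": f.ic50_ci[0],
                "ic50_ci_hi": f.ic50_ci[1],
                "verdict": f.verdict,
                "max_kill_pct": f.max_kill_pct,
            }
        )
    return pd.DataFrame(rows)
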