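"""Cross-drug summary joining calcium suppression and cytotoxicity.

One row per (drug, model): the percentage of cells still showing calcium
peaks 40 min after treatment (from the unpaired late-timepoint cohort) next
to the maximum cell-kill from the viability screen, with untested assays
explicitly marked rather than zero-filled.  The association between
residual calcium activity and kill is quantified as a Spearman rank
correlation (midrank ties); the direction is called "inverse" only when
the coefficient is negative with magnitude at or above a configurable
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SummaryRow",
    "AssociationResult",
    "build_summary_table",
    "rank_correlation",
    "summary_to_frame",
    "association_report",
]

NOT_TESTED = "not tested"


@dataclass
class SummaryRow:
    """One drug in one cell model; None marks an assay not performed."""

    drug: str
    model: str
    pct_peak_post_40min: float | None = None
    peak_dose_um: float | None = None
    max_kill_pct: float | None = None
    kill_dose_um: float | None = None

    def __post_init__(self) -> None:
        for v in (self.pct_peak_post_40min, self.max_kill_pct):
            if v is not None and not 0 <= v <= 100:
                raise ValueError(f"percentages must be in [0, 100], got {v}")

    @property
    def complete(self) -> bool:
        return self.pct_peak_post_40min is not None and self.max_kill_pct is not None


@dataclass
class AssociationResult:
    n_drugs: int
    rank_correlation: float
    direction: str  # 'inverse', 'none', or 'positive'
    defined: bool = True


def build_summary_table(
    calcium: Iterable[tuple[str, str, float, float]],
    kills: Iterable[tuple[str, str, float, float]],
) -> list[SummaryRow]:
    """Join per-(drug, model) calcium and kill records into summary rows.

    ``calcium`` records are (drug, model, pct_peak_post_40min, dose_um);
    ``kills`` records are (drug, model, max_kill_pct, dose_um). The join is
    the union of keys; a key present in only one input yields a row whose
    other assay is marked not tested (None). Duplicate keys within one
    input are an error.
    """
    ca: dict[tuple[str, str], tuple[float, float]] = {}
    for drug, model, pct, dose in calcium:
        key = (drug, model)
        if key in ca:
            raise ValueError(f"duplicate calcium record for {key}")
        ca[key] = (pct, dose)
    ki: dict[tuple[str, str], tuple[float, float]] = {}
    for drug, model, kill, dose in kills:
        key = (drug, model)
        if key in ki:
            raise ValueError(f"duplicate kill record for {key}")
        ki[key] = (kill, dose)
    rows = []
    for key in list(dict.fromkeys(list(ca) + list(ki))):
        drug, model = key
        c = ca.get(key)
        k = ki.get(key)
        rows.append(
            SummaryRow(
                drug=drug,
                model=model,
                pct_peak_post_40min=c[0] if c else None,
                peak_dose_um=c[1] if c else None,
                max_kill_pct=k[0] if k else None,
                kill_dose_um=k[1] if k else None,
            )
        )
    return rows


def rank_correlation(
    rows: Sequence[SummaryRow],
    magnitude_threshold: float = 0.5,
) -> AssociationResult:
    """Spearman correlation of residual calcium activity against max kill.

    Uses only rows with both assays present (>=3 required). A degenerate
    input (either axis constant) yields an undefined coefficient and
    direction 'none' with ``defined=False``.
    """
    pairs = [(r.pct_peak_post_40min, r.max_kill_pct) for r in rows if r.complete]
    if len(pairs) < 3:
        raise ValueError(f"rank correlation needs >=3 complete rows, got {len(pairs)}")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return AssociationResult(n_drugs=len(pairs), rank_correlation=float("nan"), direction="none", defined=False)
    rho = float(stats.spearmanr(x, y).statistic)
    if rho < 0 and abs(rho) >= magnitude_threshold:
        direction = "inverse"
    elif rho > 0 and abs(rho) >= magnitude_threshold:
        direction = "positive"
    else:
        direction = "none"
    return AssociationResult(n_drugs=len(pairs), rank_correlation=rho, direction=direction)


def summary_to_frame(rows: Sequence[SummaryRow]) -> pd.DataFrame:
    def fmt(value, dose):
        if value is None:
            return NOT_TESTED
        return f"{value:g} ({dose:g} uM)" if dose is not None else f"{value:g}"

    return pd.DataFrame(
        {
            "drug": [r.drug for r in rows],
            "model": [r.model for r in rows],
            "pct_peak_post_40min": [fmt(r.pct_peak_post_40min, r.peak_dose_um) for r in rows],
            "max_kill_pct": [fmt(r.max_kill_pct, r.kill_dose_um) for r in rows],
        }
    )


def association_report(rows: Sequence[SummaryRow], magnitude_threshold: float = 0.5) -> str:
    """Plain-text association summary across drugs, per model."""
    lines = []
    for model in sorted({r.model for r in rows}):
        sub = [r for r in rows if r.model == model]
        try:
            assoc = rank_correlation(sub, magnitude_threshold)
        except ValueError:
            lines.append(f"{model}: fewer than 3 drugs with both assays; association not computed")
            continue
        rho = "undefined" if not assoc.defined else f"{assoc.rank_correlation:+.3f}"
        lines.append(
            f"{model}: Spearman rho = {rho} over {assoc.n_drugs} drugs "
            f"(residual calcium activity vs maximum cell-kill); direction: {assoc.direction}"
        )
    return "\n".join(lines)
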