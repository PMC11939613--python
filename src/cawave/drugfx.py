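"""Paired before/after drug-effect quantification of calcium activity.

The primary outcome is the percentage of cells with at least one detected
transient, compared within the same wells before and shortly after drug
administration, and against independent cohorts at later timepoints
(repeated imaging of the same field bleaches the indicator, so 20/40-min
observations come from separate cultures and are labelled unpaired).

A drug "suppresses" activity at a timepoint when the retained-activity
fraction (post-treatment percentage over baseline percentage) falls
strictly below the suppression threshold, 0.25 by default - i.e. the cells
retain less than 25% of their baseline activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .peaks import WellActivity, pooled_activity

__all__ = ["DrugEffectResult", "paired_effect", "classify_suppression", "SUPPRESSION_THRESHOLD"]

SUPPRESSION_THRESHOLD = 0.25


@dataclass
class DrugEffectResult:
    """Baseline vs post-treatment peaking activity for one drug and dose.

    ``retained_fraction`` maps timepoint (minutes) to post/baseline activity;
    it is None (explicitly undefined, never silently NaN) when the baseline
    percentage is zero. ``paired`` records which timepoints share wells/cells
    with the baseline recording.
    """

    drug: str
    dose_um: float
    baseline_pct: float
    post_pct: dict[float, float]
    retained_fraction: dict[float, float | None]
    suppressed_flag: dict[float, bool | None]
    paired: dict[float, bool]
    threshold: float = SUPPRESSION_THRESHOLD
    baseline_n: int = 0
    post_n: dict[float, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tp in sorted(self.post_pct):
            rows.append(
                {
                    "drug": self.drug,
                    "dose_um": self.dose_um,
                    "timepoint_min": tp,
                    "baseline_pct": self.baseline_pct,
                    "post_pct": self.post_pct[tp],
                    "retained_fraction": self.retained_fraction[tp],
                    "suppressed": self.suppressed_flag[tp],
                    "paired": self.paired[tp],
                }
            )
        return pd.DataFrame(rows)


def paired_effect(
    baseline: Sequence[WellActivity],
    post: Mapping[float, Sequence[WellActivity]],
    drug: str,
    dose_um: float,
    paired_timepoints: Sequence[float] = (1.0,),
    threshold: float = SUPPRESSION_THRESHOLD,
) -> DrugEffectResult:
    """Pooled baseline and post-treatment percentages with retained fractions.

    Percentages are pooled over cells across wells (matching single
    per-condition summary numbers); per-well dispersion remains available
    via the WellActivity inputs. Timepoints listed in ``paired_timepoints``
    are flagged as sharing wells/cells with the baseline; others are
    unpaired, independently cultured cohorts.
    """
    if not baseline or not post:
        raise ValueError("paired_effect needs baseline and at least one post timepoint")
    base = pooled_activity(baseline)
    post_pct: dict[float, float] = {}
    retained: dict[float, float | None] = {}
    suppressed: dict[float, bool | None] = {}
    paired: dict[float, bool] = {}
    post_n: dict[float, int] = {}
    for tp, wells in post.items():
        p = pooled_activity(wells)
        post_pct[tp] = p.pct_peaking
        post_n[tp] = p.n_cells
        paired[tp] = tp in paired_timepoints
        if base.pct_peaking > 0:
            r = p.pct_peaking / base.pct_peaking
            retained[tp] = r
            suppressed[tp] = r < threshold
        else:
            retained[tp] = None
            suppressed[tp] = None
    return DrugEffectResult(
        drug=drug,
        dose_um=dose_um,
        baseline_pct=base.pct_peaking,
        post_pct=post_pct,
        retained_fraction=retained,
        suppressed_flag=suppressed,
        paired=paired,
        threshold=threshold,
        baseline_n=base.n_cells,
        post_n=post_n,
    )


def classify_suppression(result: DrugEffectResult, threshold: float = SUPPRESSION_THRESHOLD) -> dict[float, str]:
    """Label each timepoint 'suppressed' (retained strictly below threshold),
    'active' otherwise, or 'indeterminate' when retained activity is
    undefined (zero baseline)."""
    labels: dict[float, str] = {}
    for tp, r in result.retained_fraction.items():
        if r is None:
            labels[tp] = "indeterminate"
        else:
            labels[tp] = "suppressed" if r < threshold else "active"
    return labels
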