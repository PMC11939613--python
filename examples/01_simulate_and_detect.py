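"""Simulate a cell-line-like calcium imaging cohort and detect transients.

Generates 44 wells x 10 cells of 60 s recordings at 15 fps in which 67% of
cells carry slow-wave transients (2.5-fold, 40 s), then runs the
3.5x-baseline-SD detector and prints how well the pooled peaking
percentage and waveform parameters are recovered.
"""

import numpy as np

from cawave import peaks, synth

params = synth.CohortGenParams(
    n_wells=44,
    cells_per_well=10,
    p_peaking=0.67,
    trace_params=synth.TraceGenParams(peak_fold=2.5, peak_width_s=40.0, seed=101),
    seed=101,
)
rec = synth.generate_cohort(params)
summaries, wells, pooled = peaks.analyze_traces(rec.to_traces())

folds = [s.mean_fold for s in summaries if s.mean_fold is not None]
widths = [s.mean_width_s for s in summaries if s.mean_width_s is not None]

print(f"ground-truth peaking fraction: {100 * rec.truth_fraction():.1f}%")
print(f"detected: {pooled.n_peaking}/{pooled.n_cells} cells "
      f"({pooled.pct_peaking:.1f}%), well-level {pooled.well_mean_pct:.1f} +/- {pooled.well_sd_pct:.1f}%")
print(f"mean fold-amplitude {np.mean(folds):.2f} (truth 2.5), "
      f"mean width {np.mean(widths):.1f} s (nominal 40 s)")
print("The detected percentage tracks the generative fraction because every")
print("peaking cell carries at least one supra-threshold wave and event-free")
print("noise essentially never sustains 2 s above 3.5 baseline SDs.")
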