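"""Fit dose-response viability curves and apply the IC50 quality gates.

A plate generated with a known 4PL truth (IC50 16.66 uM) is normalized to
its DMSO controls and refit; a second, non-monotone plate (kill peaking at
a mid dose, rebounding at the top dose) shows why some drugs get an 'n/a'
verdict instead of an IC50.
"""

import numpy as np

from cawave import synth, viability

truth = 16.66
plate = synth.generate_viability_plate(
    synth.PlateGenParams(
        doses_um=tuple(np.geomspace(truth / 30, truth * 30, 7)),
        replicates=5,
        four_pl_truth=(100.0, 5.0, truth, 1.0),
        noise_cv=0.10,
        seed=42,
    ),
    drug="MIB",
)
fit = viability.fit_4pl(viability.normalize_viability(plate), seed=1)
print(f"MIB-like plate (truth IC50 {truth} uM):")
print(f"  IC50 {fit.ic50_um:.2f} uM  (95% CI {fit.ic50_ci[0]:.2f}-{fit.ic50_ci[1]:.2f}), "
      f"hill {fit.hill:.2f}, R^2 {fit.r_squared:.3f}, verdict {fit.verdict!r}")
print(f"  max cell-kill {fit.max_kill_pct:.1f}% "
      "(100 minus the lowest mean viability across doses)")

hook = synth.generate_viability_plate_from_profile(
    (0.5, 1.0, 2.0, 5.0, 10.0, 20.0), (100.0, 88.0, 55.0, 50.0, 80.0, 98.0),
    replicates=5, noise_cv=0.10, seed=7, drug="DIG",
)
fit2 = viability.fit_4pl(viability.normalize_viability(hook), n_boot=0)
print(f"DIG-like non-monotone plate: verdict {fit2.verdict!r} "
      f"(Spearman of viability vs dose {fit2.dose_spearman:+.2f} fails the monotonicity gate), "
      f"max kill {fit2.max_kill_pct:.1f}%")
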