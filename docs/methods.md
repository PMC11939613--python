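# Methods

This note documents the models, estimators, and numerical choices behind
`cawave`, and what the synthetic-data tests do and do not establish about
real recordings.

## Recording model

A cell's fluorescence trace over a recording of duration `T` (default 60 s)
at `fps` frames/s (default 15; 900 samples) is

```
F(t) = F0 · (1 − b·t/60) + Σ_k A · sin(π (t − s_k) / w) · 1[s_k ≤ t ≤ s_k + w] + ε(t)
```

* `F0` — baseline fluorescence, a.u. (default 100).
* `b` — photobleaching loss per minute as a fraction of `F0` (default 0.05;
  a multiplicative linear decay, which over a 1-min window is
  indistinguishable from an exponential and easier to verify).
* Transients are half-sine bumps of nominal width `w` (default 40 s) and
  amplitude `A = F0·(fold − 1)` (default fold 2.5), so the crest is exactly
  `F0·fold` before bleaching/noise. A half-sine rises steeply from zero,
  which keeps the threshold-crossing width close to `w`; a raised-cosine
  was considered and rejected because its shallow tails make the measured
  width ~17% narrower than nominal at these amplitudes, versus ~5–7% for
  the half-sine.
* Event times come from a Poisson process at `peaks_per_min` (default 1)
  conditioned on at least one event for cells labelled "peaking", placed
  with full support inside the recording and thinned to forbid overlap.
  The zero-truncation reflects how the phenotype is scored: a "peaking
  cell" is precisely one that shows a peak within the 1-min window. Real
  inter-peak statistics are unknown (no frequency change was reported
  under drugs), so the rate is a free parameter, not a claim.
* `ε(t)` — i.i.d. zero-mean Gaussian noise (default SD 3), a desk-scale
  proxy for shot/read noise.

Cohorts are `n_wells × cells_per_well` cells with i.i.d. Bernoulli
`p_peaking` labels. Drug transforms regenerate each cell's trace with
fresh noise while preserving identity (well:cell ids): `complete` clears
all events; `partial` lets each peaking cell retain activity with
probability `p_retain`, decided once per cell and held across timepoints;
`rebound` suppresses before `rebound_at_min` and restores after; `none` is
identical in law to baseline. The 1-min timepoint is paired with baseline;
later timepoints model the separate-culture design used to avoid
re-imaging bleach, and are labelled unpaired.

Image stacks render each cell as a disk whose pixel value in frame `t`
equals the cell's trace value, on a constant dark background, with
optional additive pixel noise — so noiseless ROI means reproduce the truth
traces exactly, and noisy means converge at `pixel_noise_sd / √area`.

Viability plates draw raw control-well fluorescence around a common mean
and dose wells at `truth(d)/100` of it, with multiplicative mean-1
lognormal noise of coefficient of variation `noise_cv`; the truth is
either a 4PL curve or an arbitrary dose→viability profile (used for flat
and non-monotone responses outside the 4PL family).

## Transient detection

A peak is a maximal run of consecutive samples with detrended value
strictly above `m·σ` (default `m = 3.5` on the SD basis; a literal
`threshold_basis="variance"` mode applies `m` to `σ²`), surviving a
minimum-width filter (default 2 s — a >10× margin below the 40–50 s waves,
but enough to make sustained noise excursions astronomically unlikely).
Width is the run length in seconds (threshold-crossing width — the
duration of one wave, matching how "wavelength" is used for these slow
signals, not an oscillation period); fold-amplitude is the raw maximum
over the baseline level.

Baseline estimation must work when a single transient covers up to ~80% of
the window, which rules out plain medians and MADs:

1. **Noise SD.** `σ = median(|ΔF|) / (√2 · 0.6745)` over first differences
   of the detrended trace. Slow waves change by ≪ σ per frame, so a
   peaking cell does not raise its own threshold. The √2 removes the
   variance doubling of differencing; the 0.6745 is the Gaussian
   median-to-SD constant.
2. **First-pass level.** A rolling (or, when the window spans the
   recording — the default for 1-min traces — global) low percentile
   (default 10th), recentred by the Gaussian quantile correction
   `z_{0.90}·σ`. `global_median` is available for traces known to be
   mostly baseline.
3. **Second pass.** Samples inside first-pass calls (padded by 5% of call
   width) are excluded and the baseline is refit: a linear fit when the
   remaining samples span at least half the recording (capturing the
   bleaching ramp), otherwise a constant median level. Detection is then
   repeated against the refit baseline. This removes the percentile
   centring bias that otherwise appears when transients dominate the
   trace.

Degenerate traces (constant, so `σ = 0` and no excursions) yield no calls.
Ties at threshold break downward: a boundary sample exactly at threshold
ends a run. Call indices are invariant under any affine gauge
`F ↦ aF + c` (a > 0); fold-amplitude, being a ratio to baseline, is
invariant under pure rescaling only — an additive offset changes it by
construction.

Known biases, visible in the synthetic recoveries and inherent to the
definitions rather than bugs: measured width underestimates the nominal
bump width by ~5% (fold 2.5, 40 s) to ~9% (fold 2.0, 50 s), because the
crossing at `3.5σ` clips the shallow bump tails and noise dips end runs
slightly early; fold-amplitude overestimates the generative fold by ~4%
because the reported maximum includes the noise maximum over the crest.

## Drug-effect quantification

Peaking percentages are pooled over cells across wells (the per-condition
summary number); per-well percentages provide the across-well mean ± SD
(reported as SD, since the error-bar convention of the original figures is
not fixed). The retained-activity fraction is `post% / baseline%`;
suppression is `retained < 0.25`, strict, with the threshold configurable.
A zero baseline makes the fraction undefined — flagged explicitly
(`None` / verdict "indeterminate"), never propagated as NaN.

## Dose–response fitting and verdicts

The 4PL is fit to individual replicate points on log10 dose.
Initialization scans a 15 × 6 grid of (log10 IC50, Hill); at each grid
point `top`/`bottom` have a closed-form linear least-squares solution, and
the best three grid points seed bounded trust-region refinements
(`scipy.optimize.least_squares`). The mirror solution
(top↔bottom, h↔−h) is mapped to the canonical orientation top ≥ bottom.
The IC50 CI is a case-resampling bootstrap over wells (500 draws, seeded,
single-start refits from the point estimate). The `top_fixed` option pins
the upper plateau for the three-parameter variant.

IC50 is reported only when all gates pass; the gates operationalize "no
interpretable IC50" (which the original screening software left
undefined) and are configurable:

* optimizer converged;
* fitted IC50 within the tested dose range widened ×[1/10, 10];
* fitted dynamic range `top − bottom ≥ 20` percentage points;
* Spearman correlation of mean viability against dose ≤ −0.5.

Maximum cell-kill is `100 − min_d(mean viability)`, clamped to [0, 100] so
super-control viability cannot produce negative kill.

## Summary and association

The cross-drug table is a pure union join on (drug, model); an assay absent
for a drug is marked "not tested", never zero-filled. The
activity–cytotoxicity association is a Spearman rank correlation with
midrank ties over drugs with both assays (≥3 required); the direction is
"inverse" only when ρ < 0 with |ρ| ≥ 0.5 (configurable). A constant axis
leaves ρ undefined and the direction "none". Spearman was chosen because
only a direction, not a coefficient, is claimed for the original
comparison, and rank correlation is invariant under the monotone
rescalings (doses, normalizations) that differ across assays.

## Problem sizes and determinism

The test suite and the acceptance script run the same stages at the sizes
the analysis design uses: 44 wells × 10 cells (n = 440) for the cell-line
cohort, 10 × 10 (n = 100) for the primary-culture cohort, 100 traces for
waveform recovery, 8 × 10 for the paired drug experiment, 1000 noise
traces for specificity, and 7-dose × 5-replicate plates at 10% CV for IC50
recovery. Every stochastic component takes an explicit integer seed;
given a seed, generated arrays are bitwise reproducible.

## What the synthetic tests do not show

The generator targets statistical, not biophysical, realism: no indicator
binding kinetics, no optics, no cell motion or focus drift, no correlated
noise, no baseline fluctuations other than linear bleaching, and
rectangular "all-or-none" transients per cell (a cell is either peaking or
silent; amplitude heterogeneity within a cell is not modelled). Passing
recoveries therefore establish that the estimators are unbiased and
specific under the stated noise model at the stated sizes — not that the
3.5σ criterion is optimal for arbitrary real recordings. Real traces with
non-Gaussian artifacts (motion spikes, focus jumps) would need the
min-width and baseline-window parameters revisited.
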