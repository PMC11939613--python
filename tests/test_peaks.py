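"""Detector correctness: baseline estimation, run-scan vs brute-force
interval enumeration, threshold-crossing width, gauge invariances."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cawave import peaks, synth
from cawave.peaks import DetectorConfig, PeakCall, _calls_from_baseline
from cawave.roi import Trace


def brute_force_calls(x, fps, trend, center, sd, cfg):
    """Oracle: test every contiguous index interval for supra-threshold
    membership and maximality, then apply the width filter."""
    det = np.asarray(x, dtype=float) - trend
    thr = cfg.threshold_mult * (sd if cfg.threshold_basis == "sd" else sd**2)
    n = len(det)
    out = []
    for a in range(n):
        for b in range(a + 1, n + 1):
            if not np.all(det[a:b] > thr):
                continue
            if a > 0 and det[a - 1] > thr:
                continue
            if b < n and det[b] > thr:
                continue
            if (b - a) / fps < cfg.min_width_s:
                continue
            peak = a + int(np.argmax(x[a:b]))
            out.append((a, b, peak))
    return out


class TestBaseline:
    def test_constant_trace(self):
        tr = Trace("c", 15.0, np.full(900, 42.0))
        bs = peaks.estimate_baseline(tr)
        assert bs.baseline_mean == pytest.approx(42.0)
        assert bs.baseline_sd == 0.0

    def test_pure_noise_sd_recovered(self, rng):
        tr = Trace("c", 15.0, 100.0 + rng.normal(0, 3.0, 900))
        bs = peaks.estimate_baseline(tr)
        assert bs.baseline_sd == pytest.approx(3.0, rel=0.15)

    def test_bleach_trend_tracked_and_residual_sd_is_noise_sd(self, rng):
        # 10%/min linear bleach; a rolling window shorter than the trace
        # must follow the ramp rather than inflate the dispersion
        t = np.arange(900) / 15.0
        base = 100.0 * (1 - 0.10 * t / 60.0)
        tr = Trace("c", 15.0, base + rng.normal(0, 2.0, 900))
        cfg = DetectorConfig(rolling_window_s=20.0)
        bs = peaks.estimate_baseline(tr, cfg)
        assert bs.baseline_sd == pytest.approx(2.0, rel=0.2)  # noise, not the 10-unit ramp
        assert bs.baseline_mean == pytest.approx(base.mean(), abs=1.5)
        assert np.corrcoef(bs.trend, base)[0, 1] > 0.9

    def test_trace_shorter_than_window_raises(self):
        tr = Trace("c", 15.0, np.zeros(300))  # 20 s
        with pytest.raises(ValueError, match="shorter than"):
            peaks.estimate_baseline(tr, DetectorConfig(rolling_window_s=60.0))


class TestDetect:
    def test_constant_trace_yields_no_calls(self):
        assert peaks.detect_peaks(Trace("c", 15.0, np.full(900, 5.0))) == []

    def test_pure_noise_yields_no_calls(self, rng):
        tr = Trace("c", 15.0, 100.0 + rng.normal(0, 3.0, 900))
        assert peaks.detect_peaks(tr) == []

    def test_single_noiseless_bump_width_matches_crossing_oracle(self):
        p = synth.TraceGenParams(noise_sd=0.0, bleach_frac_per_min=0.0, seed=11)
        tr = synth.generate_trace(p, peaking=True)
        calls = peaks.detect_peaks(tr)
        assert len(calls) == 1
        c = calls[0]
        assert c.fold_amplitude == pytest.approx(2.5, abs=0.01)
        # closed-form crossing width of a half-sine bump at the detector's
        # threshold (center is exact here, so excess = mult * estimated sd)
        sd = peaks.estimate_baseline(tr).baseline_sd
        excess = 3.5 * sd / (p.baseline_f0 * (p.peak_fold - 1))
        expected = p.peak_width_s * (1 - 2 * np.arcsin(excess) / np.pi)
        assert c.width_s == pytest.approx(expected, abs=2 / p.fps)

    def test_run_scan_equals_brute_force_on_short_traces(self, rng):
        cfg = DetectorConfig(min_width_s=0.3)
        for _ in range(60):
            n = int(rng.integers(20, 200))
            fps = 10.0
            x = rng.normal(0, 1, n).cumsum() * 0.1 + rng.normal(0, 1, n)
            trend = np.full(n, np.median(x))
            sd = 0.8
            got = _calls_from_baseline(x, fps, trend, float(np.median(x)) or 1.0, sd, cfg)
            expected = brute_force_calls(x, fps, trend, float(np.median(x)) or 1.0, sd, cfg)
            assert [(c.onset_idx, c.offset_idx, c.peak_idx) for c in got] == expected

    def test_raising_threshold_never_adds_calls(self, rng):
        p = synth.TraceGenParams(seed=13)
        tr = synth.generate_trace(p, peaking=True)
        counts = [
            len(peaks.detect_peaks(tr, DetectorConfig(threshold_mult=m))) for m in (2.0, 3.5, 5.0, 20.0, 60.0)
        ]
        assert counts == sorted(counts, reverse=True)

    @given(scale=st.floats(0.1, 50.0), offset=st.floats(-50.0, 200.0))
    def test_call_indices_invariant_under_affine_gauge(self, scale, offset):
        tr = synth.generate_trace(synth.TraceGenParams(seed=21), peaking=True)
        ref = peaks.detect_peaks(tr)
        tr2 = Trace(tr.cell_id, tr.fps, scale * tr.values + offset)
        got = peaks.detect_peaks(tr2)
        assert [(c.onset_idx, c.offset_idx) for c in got] == [(c.onset_idx, c.offset_idx) for c in ref]

    def test_fold_amplitude_invariant_under_pure_rescaling(self):
        tr = synth.generate_trace(synth.TraceGenParams(seed=22), peaking=True)
        ref = peaks.detect_peaks(tr)
        got = peaks.detect_peaks(Trace(tr.cell_id, tr.fps, 7.0 * tr.values))
        assert [c.fold_amplitude for c in got] == pytest.approx([c.fold_amplitude for c in ref], rel=1e-9)

    def test_variance_basis_lowers_threshold_for_small_sd(self):
        # with sd < 1, 3.5*var < 3.5*sd: literal variance thresholding is laxer
        tr = synth.generate_trace(synth.TraceGenParams(noise_sd=0.5, seed=30), peaking=True)
        n_sd = len(peaks.detect_peaks(tr, DetectorConfig(threshold_basis="sd")))
        n_var = len(peaks.detect_peaks(tr, DetectorConfig(threshold_basis="variance")))
        assert n_var >= n_sd >= 1

    def test_peak_call_invariants(self):
        tr = synth.generate_trace(synth.TraceGenParams(seed=40), peaking=True)
        for c in peaks.detect_peaks(tr):
            assert c.onset_idx <= c.peak_idx < c.offset_idx
            assert c.fold_amplitude >= 1.0
            assert c.width_s > 0
        with pytest.raises(ValueError):
            PeakCall(onset_idx=5, offset_idx=10, peak_idx=12, fold_amplitude=2.0, width_s=1.0)


class TestSummaries:
    def _call(self, fold, width):
        return PeakCall(onset_idx=0, offset_idx=int(width * 15), peak_idx=1, fold_amplitude=fold, width_s=width)

    def test_empty_calls(self):
        tr = Trace("w:c", 15.0, np.zeros(10))
        s = peaks.summarize_cell(tr, [])
        assert (s.has_peak, s.n_peaks, s.mean_fold, s.mean_width_s) == (False, 0, None, None)

    def test_mean_fold_and_width(self):
        tr = Trace("w:c", 15.0, np.zeros(10))
        s = peaks.summarize_cell(tr, [self._call(2.0, 30.0), self._call(2.5, 50.0), self._call(3.0, 40.0)])
        assert s.n_peaks == 3 and s.has_peak
        assert s.mean_fold == pytest.approx(2.5)
        assert s.mean_width_s == pytest.approx(40.0)

    def test_well_activity_percentages(self):
        def cell(i, has):
            return peaks.CellSummary(cell_id=f"c{i}", has_peak=has, n_peaks=int(has), mean_fold=None, mean_width_s=None)

        w = peaks.well_activity([cell(i, i < 3) for i in range(10)], "W1")
        assert w.pct_peaking == pytest.approx(30.0)
        full = peaks.well_activity([cell(i, True) for i in range(10)], "W2")
        assert full.pct_peaking == 100.0
        with pytest.raises(ValueError):
            peaks.well_activity([], "W3")

    def test_pooled_activity_across_wells(self):
        wells = [peaks.WellActivity("a", 10, 10), peaks.WellActivity("b", 10, 4)]
        pooled = peaks.pooled_activity(wells)
        assert pooled.pct_peaking == pytest.approx(70.0)
        assert pooled.well_mean_pct == pytest.approx(70.0)
        assert pooled.well_sd_pct == pytest.approx(np.std([100, 40], ddof=1))
        assert pooled.n_cells == 20

    def test_analyze_traces_groups_by_well_prefix(self):
        rec = synth.generate_cohort(synth.CohortGenParams(n_wells=3, cells_per_well=4, p_peaking=1.0, seed=2))
        summaries, wells, pooled = peaks.analyze_traces(rec.to_traces())
        assert len(summaries) == 12
        assert sorted(w.well_id for w in wells) == ["W001", "W002", "W003"]
        assert pooled.n_wells == 3
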