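"""Generator contracts: reproducibility, analytic trace model, cohort labels,
drug transforms, plate normalization truth."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from cawave import synth


class TestTraceGeneration:
    def test_constant_without_noise_or_events(self):
        p = synth.TraceGenParams(noise_sd=0.0, bleach_frac_per_min=0.0, baseline_f0=100.0)
        tr = synth.generate_trace(p, peaking=False)
        assert np.array_equal(tr.values, np.full(900, 100.0))

    def test_default_frame_count_is_900(self):
        assert synth.TraceGenParams().n_frames == 900
        assert synth.generate_trace(synth.TraceGenParams(), peaking=True).n_frames == 900

    def test_single_event_reaches_fold_maximum(self):
        # noiseless, no bleach: peak maximum must be exactly f0*fold
        p = synth.TraceGenParams(noise_sd=0.0, bleach_frac_per_min=0.0, peak_fold=2.5, seed=5)
        tr = synth.generate_trace(p, peaking=True)
        centers = synth.draw_event_centers(p, np.random.default_rng(5))
        assert len(centers) >= 1
        # sampling grid may miss the exact crest by up to half a frame
        crest = 250.0 - 150.0 * (1 - np.sin(np.pi * (0.5 - 0.5 / (p.fps * p.peak_width_s))))
        assert crest <= tr.values.max() <= 250.0

    def test_seeded_generation_is_bitwise_reproducible(self):
        p = synth.TraceGenParams(seed=77)
        a = synth.generate_trace(p, peaking=True)
        b = synth.generate_trace(p, peaking=True)
        assert np.array_equal(a.values, b.values)

    @given(
        fold=st.floats(1.2, 3.0),
        width=st.floats(10.0, 50.0),
        bleach=st.floats(0.0, 0.3),
        seed=st.integers(0, 10_000),
    )
    def test_noiseless_trace_matches_analytic_model(self, fold, width, bleach, seed):
        p = synth.TraceGenParams(
            noise_sd=0.0, bleach_frac_per_min=bleach, peak_fold=fold, peak_width_s=width, seed=seed
        )
        tr = synth.generate_trace(p, peaking=True)
        centers = synth.draw_event_centers(p, np.random.default_rng(seed))
        t = np.arange(p.n_frames) / p.fps
        assert np.allclose(tr.values, synth.trace_model(p, centers, t), atol=1e-12)

    def test_events_do_not_overlap_and_fit_inside_recording(self):
        p = synth.TraceGenParams(peak_width_s=10.0, peaks_per_min=6.0, seed=9)
        for s in range(30):
            centers = synth.draw_event_centers(p, np.random.default_rng(s))
            assert len(centers) >= 1
            assert all(5.0 <= c <= 55.0 for c in centers)
            gaps = np.diff(centers)
            assert np.all(gaps >= 10.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"baseline_f0": 0.0},
            {"fps": 0.0},
            {"peak_width_s": -1.0},
            {"noise_sd": -0.1},
            {"bleach_frac_per_min": 1.0},
            {"peak_fold": 0.5},
            {"duration_s": 0.03},
        ],
    )
    def test_invalid_parameters_raise(self, kwargs):
        with pytest.raises(ValueError):
            synth.TraceGenParams(**kwargs)


class TestCohorts:
    def test_p_one_labels_all_peaking(self):
        rec = synth.generate_cohort(synth.CohortGenParams(n_wells=3, cells_per_well=4, p_peaking=1.0, seed=0))
        assert all(c.peaking for c in rec.cells)
        assert len(rec.cells) == 12

    def test_label_fraction_within_binomial_interval(self):
        rec = synth.generate_cohort(synth.CohortGenParams(n_wells=44, cells_per_well=10, p_peaking=0.5, seed=3))
        n = len(rec.cells)
        lo, hi = stats.binom.interval(0.99, n, 0.5)
        assert lo / n <= rec.truth_fraction() <= hi / n

    def test_non_peaking_cells_have_no_events(self):
        p = synth.TraceGenParams(noise_sd=0.0, bleach_frac_per_min=0.0)
        rec = synth.generate_cohort(
            synth.CohortGenParams(n_wells=2, cells_per_well=5, p_peaking=0.0, trace_params=p, seed=1)
        )
        for c in rec.cells:
            assert np.array_equal(c.values, np.full(900, 100.0))


class TestDrugEffects:
    def _cohort(self, p_peaking=1.0, seed=4):
        return synth.generate_cohort(
            synth.CohortGenParams(n_wells=2, cells_per_well=5, p_peaking=p_peaking, seed=seed)
        )

    def test_complete_mode_strips_all_events(self):
        rec = self._cohort()
        post = synth.apply_drug_effect(rec, synth.DrugEffectSpec(mode="complete"), seed=1)
        for tp, r in post.items():
            assert all(not c.peaking for c in r.cells)

    def test_none_mode_preserves_labels_and_identity(self):
        rec = self._cohort(p_peaking=0.6)
        post = synth.apply_drug_effect(rec, synth.DrugEffectSpec(mode="none"), seed=1)
        for r in post.values():
            assert [c.label for c in r.cells] == [c.label for c in rec.cells]
            assert [c.peaking for c in r.cells] == [c.peaking for c in rec.cells]
            # fresh noise realization, not a copy
            assert not np.array_equal(r.cells[0].values, rec.cells[0].values)

    def test_rebound_suppresses_then_restores(self):
        rec = self._cohort()
        post = synth.apply_drug_effect(
            rec, synth.DrugEffectSpec(mode="rebound", rebound_at_min=30.0, timepoints_min=(20.0, 40.0)), seed=2
        )
        assert all(not c.peaking for c in post[20.0].cells)
        assert [c.peaking for c in post[40.0].cells] == [c.peaking for c in rec.cells]

    def test_partial_mode_retain_decision_is_consistent_across_timepoints(self):
        rec = self._cohort()
        post = synth.apply_drug_effect(
            rec, synth.DrugEffectSpec(mode="partial", p_retain=0.5, timepoints_min=(1.0, 20.0)), seed=3
        )
        assert [c.peaking for c in post[1.0].cells] == [c.peaking for c in post[20.0].cells]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown drug-effect mode"):
            synth.DrugEffectSpec(mode="wash")


class TestImageStack:
    def test_noiseless_roi_mean_equals_truth(self):
        from cawave import roi

        stack = synth.generate_image_stack(
            synth.CohortGenParams(n_wells=1, cells_per_well=3, p_peaking=1.0, seed=2),
            synth.StackGeometry(pixel_noise_sd=0.0),
        )
        for r, truth in zip(stack.roi_truth, stack.per_cell_truth):
            got = roi.extract_roi_trace(stack.frames, r, fps=truth.fps)
            assert np.allclose(got.values, truth.values)

    def test_noisy_roi_mean_within_standard_error(self):
        from cawave import roi

        geo = synth.StackGeometry(pixel_noise_sd=4.0)
        stack = synth.generate_image_stack(
            synth.CohortGenParams(n_wells=1, cells_per_well=10, p_peaking=0.5, seed=6), geo
        )
        for r, truth in zip(stack.roi_truth, stack.per_cell_truth):
            got = roi.extract_roi_trace(stack.frames, r, fps=truth.fps)
            area = int(roi.disk_mask(stack.frames.shape[1:], r).sum())
            tol = 3.0 * geo.pixel_noise_sd / np.sqrt(area)
            assert np.max(np.abs(got.values - truth.values)) <= tol * 2  # max over 900 frames

    def test_infeasible_packing_raises(self):
        geo = synth.StackGeometry(frame_shape=(32, 32), radius_px=(10.0, 12.0), max_placement_tries=50)
        with pytest.raises(RuntimeError, match="could not place"):
            synth.generate_image_stack(synth.CohortGenParams(n_wells=1, cells_per_well=6, seed=0), geo)


class TestViabilityPlates:
    def test_noiseless_plate_reproduces_4pl_truth(self):
        from cawave import viability

        p = synth.PlateGenParams(
            doses_um=(1.0, 2.0, 5.0, 10.0, 20.0), four_pl_truth=(100.0, 5.0, 10.0, 1.0), noise_cv=0.0, seed=0
        )
        table = viability.normalize_viability(synth.generate_viability_plate(p))
        truth = synth.four_pl(table.data["dose_um"].to_numpy(), 100.0, 5.0, 10.0, 1.0)
        assert np.allclose(table.data["viability_pct"], truth)
        # midpoint identity at d = IC50
        at_ic50 = table.data.loc[table.data["dose_um"] == 10.0, "viability_pct"]
        assert np.allclose(at_ic50, (100.0 + 5.0) / 2)

    def test_plate_schema_and_controls(self):
        p = synth.PlateGenParams(seed=1)
        plate = synth.generate_viability_plate(p, drug="MIB")
        assert list(plate.columns) == ["well", "condition", "dose_um", "raw_fluorescence"]
        ctrl = plate[plate["condition"] == "DMSO"]
        assert len(ctrl) == p.n_control_wells
        assert (ctrl["dose_um"] == 0).all()

    def test_invalid_doses_rejected(self):
        with pytest.raises(ValueError):
            synth.PlateGenParams(doses_um=(5.0, 1.0))
        with pytest.raises(ValueError):
            synth.PlateGenParams(four_pl_truth=(10.0, 50.0, 1.0, 1.0))
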