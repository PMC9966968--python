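import numpy as np
import pandas as pd
import pytest

from ventpulse.annotate import (
    annotate_recording,
    annotation_table,
    chest_wall_elastance,
    compute_pmus,
    compute_ptp,
    compute_volume,
    label_weak,
    predicted_vc,
    validate_annotations,
)
from ventpulse.dataio import BreathSegment, PatientProfile, Recording
from ventpulse.pipeline import truth_segments
from ventpulse.segment import segment_breaths
from ventpulse.simulate import CohortEntry


class TestElastance:
    def test_predicted_vc_hand_values(self):
        assert predicted_vc("male", 70, 175) == pytest.approx(3463.25)
        assert predicted_vc("female", 70, 160) == pytest.approx(2353.6)

    def test_vc_domain_errors(self):
        with pytest.raises(ValueError):
            predicted_vc("male", 247, 175)
        with pytest.raises(ValueError):
            predicted_vc("female", 216, 160)
        with pytest.raises(ValueError):
            predicted_vc("male", -5, 175)

    def test_chest_wall_elastance_default_mode(self):
        assert chest_wall_elastance(3463.25) == pytest.approx(7.219, abs=1e-3)
        assert chest_wall_elastance(2500.0) == pytest.approx(10.0)
        # inverse proportionality: doubling VC halves Ecw
        assert chest_wall_elastance(5000.0) == pytest.approx(
            chest_wall_elastance(2500.0) / 2
        )

    def test_chest_wall_elastance_literal_mode(self):
        assert chest_wall_elastance(3463.25, mode="literal") == pytest.approx(
            0.025 * 3463.25
        )


class TestVolume:
    def test_constant_flow_integral(self):
        v = compute_volume(np.full(101, 0.5), fs=100.0)
        assert v[0] == 0.0
        assert v[-1] == pytest.approx(0.5, abs=1e-9)

    def test_sine_flow_returns_to_zero(self):
        t = np.linspace(0, 1, 401)
        v = compute_volume(np.sin(2 * np.pi * t), fs=400.0)
        assert abs(v[-1]) < 1e-4

    def test_simulated_vt_matches_integrator_state(self, sim_recording):
        rec, gt = sim_recording
        v = compute_volume(rec.flow, rec.fs)
        for onset, ie in zip(gt.onset_idx[:5], gt.insp_end_idx[:5]):
            vt_seg = compute_volume(rec.flow[onset : ie + 1], rec.fs)[-1]
            assert vt_seg == pytest.approx(v[ie] - v[onset], abs=1e-9)


class TestPmus:
    def _passive_recording(self, ecw=8.0, rcw=1.5, pes_endexp=5.0):
        n = 500
        fs = 100.0
        rng = np.random.default_rng(0)
        flow = 0.5 * np.sin(2 * np.pi * np.arange(n) / n)
        vol = compute_volume(flow, fs)
        pes = pes_endexp + ecw * vol + rcw * flow
        return Recording("p", fs, np.arange(n) / fs, flow,
                         paw=np.full(n, 7.0), pes=pes)

    def test_passive_breath_gives_zero_pmus(self):
        rec = self._passive_recording()
        seg = BreathSegment.from_indices(0, 250, 499, rec.fs)
        prof = PatientProfile("male", 70, 175, pes_endexp=5.0)
        pmus = compute_pmus(rec, seg, prof, ecw=8.0, rcw=1.5)
        np.testing.assert_allclose(pmus, 0.0, atol=1e-9)

    def test_hand_computed_sample(self):
        # V=0.5 L, ecw=8, flow=0.5, rcw=1.5, pes_endexp=5, pes=3 -> 6.75
        n = 201
        fs = 100.0
        flow = np.full(n, 0.5)  # V(t=1 s) = 0.5 L exactly
        rec = Recording("p", fs, np.arange(n) / fs, flow,
                        paw=np.full(n, 7.0), pes=np.full(n, 3.0))
        seg = BreathSegment.from_indices(0, 150, 200, fs)
        prof = PatientProfile("male", 70, 175, pes_endexp=5.0)
        pmus = compute_pmus(rec, seg, prof, ecw=8.0, rcw=1.5)
        assert compute_volume(flow, fs)[100] == pytest.approx(0.5, abs=1e-12)
        assert pmus[100] == pytest.approx(6.75, abs=1e-9)

    def test_invalid_segment_refused(self, sim_recording, std_profile):
        rec, _ = sim_recording
        seg = BreathSegment.from_indices(0, 50, 100, rec.fs, valid=False,
                                         exclusion_reason="artifact")
        with pytest.raises(ValueError, match="invalid_segment"):
            compute_pmus(rec, seg, std_profile, ecw=7.0)

    def test_reconstruction_matches_truth(self, sim_recording, std_mech,
                                          std_profile):
        rec, gt = sim_recording
        entry = CohortEntry(rec, gt, std_profile, std_mech, None)
        for seg in truth_segments(entry):
            pmus = compute_pmus(rec, seg, std_profile, ecw=std_mech.ecw,
                                rcw=std_mech.rcw)
            ref = gt.pmus_true[seg.onset_idx : seg.breath_end_idx]
            assert np.max(np.abs(pmus - ref)) < 1e-6


class TestPtp:
    def test_constant_pmus(self):
        fs = 100.0
        seg = BreathSegment.from_indices(0, 100, 300, fs)
        pmus = np.full(300, 10.0)
        ptp_b, ptp_m = compute_ptp(pmus, seg, fs)
        assert ptp_b == pytest.approx(10.0)
        assert ptp_m == pytest.approx(200.0)  # rr = 60/3 = 20

    def test_zero_pmus(self):
        fs = 100.0
        seg = BreathSegment.from_indices(0, 100, 300, fs)
        assert compute_ptp(np.zeros(300), seg, fs) == (0.0, 0.0)

    @pytest.mark.parametrize("c", [0.5, 2.0, 7.3])
    def test_scaling_linearity(self, c):
        fs = 100.0
        seg = BreathSegment.from_indices(0, 120, 280, fs)
        rng = np.random.default_rng(3)
        pmus = rng.standard_normal(280) + 4.0
        b1, m1 = compute_ptp(pmus, seg, fs)
        b2, m2 = compute_ptp(c * pmus, seg, fs)
        assert b2 == pytest.approx(c * b1)
        assert m2 == pytest.approx(c * m1)


class TestLabel:
    def test_threshold_boundary_convention(self):
        assert label_weak(49.99) is True
        assert label_weak(50.0) is False
        assert label_weak(136.0) is False

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            label_weak(float("nan"))

    def test_monotone_in_ptp(self):
        labels = [label_weak(x) for x in np.linspace(0, 120, 200)]
        assert sorted(labels, reverse=True) == labels


class TestValidation:
    def _tables(self, sim_recording, std_mech, std_profile):
        rec, gt = sim_recording
        segs = segment_breaths(rec)
        ann = annotate_recording(rec, segs, std_profile, ecw=std_mech.ecw,
                                 rcw=std_mech.rcw)
        table = annotation_table(rec, ann)
        ref = gt.to_table(rec.patient_id, rec.fs).rename(
            columns={"ptp_min_true": "ptp_min", "weak_true": "weak"}
        )
        return table, ref

    def test_self_comparison_is_perfect(self, sim_recording, std_mech,
                                        std_profile):
        table, _ = self._tables(sim_recording, std_mech, std_profile)
        rep = validate_annotations(table, table)
        assert rep.pct_segments_correct == 100.0
        assert rep.median_abs_ptp_diff == 0.0
        assert rep.pct_label_agreement == 100.0

    def test_single_flipped_label_counted(self, sim_recording, std_mech,
                                          std_profile):
        table, _ = self._tables(sim_recording, std_mech, std_profile)
        ref = table.copy()
        ref.loc[ref.index[:2], "weak"] = ~ref.loc[ref.index[:2], "weak"].astype(bool)
        rep = validate_annotations(table, ref)
        expected = 100.0 * (len(table) - 2) / len(table)
        assert rep.pct_label_agreement == pytest.approx(expected)

    def test_against_simulator_truth(self, sim_recording, std_mech,
                                     std_profile):
        table, ref = self._tables(sim_recording, std_mech, std_profile)
        rep = validate_annotations(table, ref)
        assert rep.pct_segments_correct >= 99.0
        assert rep.pct_label_agreement >= 99.0
        assert rep.median_abs_ptp_diff < 5.0

    def test_disjoint_patients_error(self, sim_recording, std_mech,
                                     std_profile):
        table, _ = self._tables(sim_recording, std_mech, std_profile)
        other = table.copy()
        other["patient_id"] = "someone_else"
        with pytest.raises(ValueError, match="overlap"):
            validate_annotations(table, other)
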