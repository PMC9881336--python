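import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hemigait import metrics as mx
from hemigait import pipeline, synthgait
from hemigait.markerio import MarkerTrial, ParticipantMeta
from hemigait.metrics import MetricError


class TestAsymmetryIndex:
    @pytest.mark.parametrize("p,n,expected", [(0.5, 0.5, 0.0), (0.6, 0.4, 0.2), (0.75, 0.25, 0.5)])
    def test_hand_computed_values(self, p, n, expected):
        assert mx.asymmetry_index(p, n) == pytest.approx(expected)

    @pytest.mark.parametrize("p,n", [(0.0, 0.5), (-0.1, 0.5), (0.5, 0.0)])
    def test_non_positive_inputs_rejected(self, p, n):
        with pytest.raises(MetricError):
            mx.asymmetry_index(p, n)

    @given(
        p=st.floats(min_value=1e-3, max_value=10.0),
        n=st.floats(min_value=1e-3, max_value=10.0),
    )
    def test_limb_swap_invariance_and_bounds(self, p, n):
        idx = mx.asymmetry_index(p, n)
        assert idx == mx.asymmetry_index(n, p)
        assert 0.0 <= idx < 1.0


def _static_trial(markers, n=8):
    """Trial whose markers hold a fixed pose (constant over n frames)."""
    full = {k: np.tile(np.asarray(v, float), (n, 1)) for k, v in markers.items()}
    return MarkerTrial(
        participant_id="pose", group="neurotypical", paretic_side="none",
        belt_speed=1.0, sampling_rate=100.0, markers=full,
    )


def _single_stride_table(limb="right", fs=0, to=1, nxt=3):
    rows = [
        dict(limb=limb, fs_frame=fs, toe_off_frame=to, next_fs_frame=nxt,
             stride_time=(nxt - fs) / 100, stance_time=(to - fs) / 100,
             swing_time=(nxt - to) / 100, single_support=0.3, double_support=0.1,
             flagged=False)
        for fs, to, nxt in ((fs, to, nxt), (nxt, nxt + 1, nxt + 3))
    ]
    from hemigait.events import StrideTable

    return StrideTable(
        sampling_rate=100.0,
        foot_strikes={limb: np.array([fs, nxt]), "left" if limb == "right" else "right": np.array([])},
        toe_offs={limb: np.array([to, nxt + 1]), "left" if limb == "right" else "right": np.array([])},
        strides=pd.DataFrame(rows),
    )


class TestKneeAngle:
    def test_collinear_markers_give_zero_flexion(self):
        trial = _static_trial({
            ("greater_trochanter", "right"): (0, 0, 1.0),
            ("lateral_femoral_epicondyle", "right"): (0, 0, 0.5),
            ("lateral_malleolus", "right"): (0, 0, 0.0),
        })
        assert mx.knee_angle_series(trial, "right")[0] == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_segments_give_ninety_degrees(self):
        trial = _static_trial({
            ("greater_trochanter", "right"): (0, 0, 0.5),
            ("lateral_femoral_epicondyle", "right"): (0, 0, 0.0),
            ("lateral_malleolus", "right"): (0.5, 0, 0.0),
        })
        assert mx.knee_angle_series(trial, "right")[0] == pytest.approx(90.0, abs=1e-9)


class TestTrailingLimbAngle:
    def test_foot_directly_below_hip_gives_zero(self):
        trial = _static_trial({
            ("greater_trochanter", "right"): (0, 0, 0.9),
            ("fifth_metatarsal", "right"): (0, 0, 0.0),
        })
        val, _ = mx.trailing_limb_angle(trial, _single_stride_table(), "right")
        assert val == pytest.approx(0.0, abs=1e-9)

    def test_hand_trigonometry_case(self):
        """GT=(0,0,0.9), MT5=(-0.3,0,0): atan2(0.3, 0.9) = 18.43 deg."""
        trial = _static_trial({
            ("greater_trochanter", "right"): (0, 0, 0.9),
            ("fifth_metatarsal", "right"): (-0.3, 0, 0.0),
        })
        val, _ = mx.trailing_limb_angle(trial, _single_stride_table(), "right")
        assert val == pytest.approx(np.degrees(np.arctan2(0.3, 0.9)), abs=1e-9)
        assert val == pytest.approx(18.43, abs=0.01)


class TestCircumduction:
    def test_planar_gait_gives_zero(self):
        trial = _static_trial({("lateral_malleolus", "right"): (0, 0.1, 0.1)})
        val, _ = mx.circumduction(trial, _single_stride_table(), "right")
        assert val == 0.0

    def test_hand_subtraction_case(self):
        """Stance mean Y = -0.10 m (right side), swing peak lateral -0.145 -> 0.045 m."""
        y = np.array([-0.10, -0.10, -0.145, -0.10, -0.10, -0.12, -0.10, -0.10])
        arr = np.column_stack([np.zeros(8), y, np.zeros(8)])
        trial = MarkerTrial("t", "neurotypical", "none", 1.0, 100.0,
                            {("lateral_malleolus", "right"): arr})
        st_table = _single_stride_table("right", fs=0, to=1, nxt=3)
        val, per = mx.circumduction(trial, st_table, "right")
        assert per[0] == pytest.approx(0.045, abs=1e-12)

    def test_medial_displacement_floors_at_zero(self):
        y = np.array([0.10, 0.10, 0.06, 0.10, 0.10, 0.08, 0.10, 0.10])  # left limb moving medially
        arr = np.column_stack([np.zeros(8), y, np.zeros(8)])
        trial = MarkerTrial("t", "neurotypical", "none", 1.0, 100.0,
                            {("lateral_malleolus", "left"): arr})
        val, _ = mx.circumduction(trial, _single_stride_table("left"), "left")
        assert val == 0.0


class TestHipHiking:
    def test_level_pelvis_gives_zero(self):
        trial = _static_trial({
            ("iliac_crest", "right"): (0, -0.15, 1.0),
            ("iliac_crest", "left"): (0, 0.15, 1.0),
        })
        val, _ = mx.hip_hiking(trial, _single_stride_table(), "right")
        assert val == 0.0

    def test_hand_trigonometry_case(self):
        """Crests 0.30 m apart, swing-side crest 0.02 m higher at swing peak,
        level reference: atan2(0.02, 0.30) = 3.81 deg."""
        zr = np.array([1.0, 1.0, 1.02, 1.0, 1.0, 1.0, 1.0, 1.0])
        right = np.column_stack([np.zeros(8), np.full(8, -0.15), zr])
        left = np.column_stack([np.zeros(8), np.full(8, 0.15), np.full(8, 1.0)])
        trial = MarkerTrial("t", "neurotypical", "none", 1.0, 100.0,
                            {("iliac_crest", "right"): right, ("iliac_crest", "left"): left})
        val, per = mx.hip_hiking(trial, _single_stride_table("right"), "right")
        assert per[0] == pytest.approx(np.degrees(np.arctan2(0.02, 0.30)), abs=1e-9)
        assert per[0] == pytest.approx(3.81, abs=0.01)


class TestStepLengths:
    def test_hand_subtraction_case(self):
        """Leading malleolus at X=0.30, trailing at X=-0.25: step length 0.55 m."""
        lead = np.tile([0.30, 0.0, 0.1], (8, 1))
        trail = np.tile([-0.25, 0.0, 0.1], (8, 1))
        trial = MarkerTrial("t", "neurotypical", "none", 1.0, 100.0,
                            {("lateral_malleolus", "right"): lead,
                             ("lateral_malleolus", "left"): trail})
        table = _single_stride_table("right")
        table.strides = pd.concat(
            [table.strides, table.strides.assign(limb="left")], ignore_index=True
        )
        sp, sn = mx.step_lengths(trial, table, "right")
        assert sp[0] == pytest.approx(0.55)


class TestSimulatorOracle:
    def test_all_seven_metrics_recover_ground_truth(self, asymmetric_trial):
        trial, truth = asymmetric_trial
        rec = pipeline.process_trial(trial, apply_filter=False)
        tol = dict(sla=0.01, dlsta=0.01, slsta=0.01, knee_flex_deg=1.0,
                   tla_deg=1.0, circumduction_m=0.005, hip_hike_deg=1.0)
        for name, t in tol.items():
            assert getattr(rec, name) == pytest.approx(truth.true_metrics[name], abs=t), name

    def test_symmetric_trial_gives_zero_asymmetries(self, symmetric_trial):
        trial, _ = symmetric_trial
        rec = pipeline.process_trial(trial, apply_filter=False)
        assert rec.sla == pytest.approx(0.0, abs=0.01)
        assert rec.dlsta == pytest.approx(0.0, abs=0.01)
        assert rec.slsta == pytest.approx(0.0, abs=0.01)

    def test_angles_invariant_lengths_scale_under_spatial_scaling(self, asymmetric_trial):
        trial, _ = asymmetric_trial
        rec0 = pipeline.process_trial(trial, apply_filter=False)
        scaled = trial.copy_with({k: 2.0 * v for k, v in trial.markers.items()})
        rec2 = pipeline.process_trial(scaled, apply_filter=False)
        assert rec2.knee_flex_deg == pytest.approx(rec0.knee_flex_deg, abs=1e-6)
        assert rec2.tla_deg == pytest.approx(rec0.tla_deg, abs=1e-6)
        assert rec2.hip_hike_deg == pytest.approx(rec0.hip_hike_deg, abs=1e-6)
        assert rec2.circumduction_m == pytest.approx(2.0 * rec0.circumduction_m, rel=1e-6)
        # asymmetry indices are scale-free
        assert rec2.sla == pytest.approx(rec0.sla, abs=1e-9)

    def test_two_bins_over_periodic_data_give_identical_records(self):
        p = synthgait.GaitParams(n_strides=12, noise_sd=0.0, seed=4,
                                 step_length_left=0.5, step_length_right=0.5)
        trial, _ = synthgait.generate_trial(p)
        # two windows each containing exactly 4 stride periods (T = 1.0 s)
        rec_a = pipeline.process_trial(trial, ("middle_seconds", 4), apply_filter=False)
        rec_b = pipeline.process_trial(trial, ("final_seconds", 4), apply_filter=False)
        for name in ("sla", "dlsta", "slsta", "knee_flex_deg", "tla_deg",
                     "circumduction_m", "hip_hike_deg"):
            assert getattr(rec_a, name) == pytest.approx(getattr(rec_b, name), abs=1e-6)


class TestInclusionFilter:
    def _meta(self, speeds, calib=True, pid="X"):
        return ParticipantMeta(pid, "stroke", "left", 60.0, list(speeds),
                               le_fugl_meyer=20, has_calibration=calib)

    def test_slowest_above_threshold_included(self):
        inc, exc = mx.apply_inclusion_filter([self._meta([0.21, 0.26, 0.31, 0.56])])
        assert len(inc) == 1 and not exc

    def test_boundary_is_strict(self):
        inc, exc = mx.apply_inclusion_filter([self._meta([0.20, 0.4])])
        assert not inc and "not >" in exc[0][1]

    def test_missing_calibration_excluded_with_reason(self):
        inc, exc = mx.apply_inclusion_filter([self._meta([0.5], calib=False)])
        assert not inc and exc[0][1] == "no standing calibration"
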