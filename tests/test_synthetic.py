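"""Generator contracts: factorial shape, determinism, noise model, waveforms."""

import numpy as np
import pandas as pd
import pytest

from avaflow import (GroundTruth, SyntheticConfig, compute_q_inst,
                     co_flow_map, generate_peak_dataset, generate_recordings,
                     inject_missing, sigmoid_ava)


class TestGroundTruth:
    def test_native_grade_must_be_unity(self):
        with pytest.raises(ValueError):
            GroundTruth(s_star_per_grade={"a": 1.1, "b": 1.3})

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            GroundTruth(noise_sd_ava=-0.01)

    def test_co_flow_map_matches_anchor_regression(self):
        # independent closed-form simple-regression oracle on the anchors
        co = np.array([0.5, 2.5, 5.0])
        q = np.array([0.24, 0.57, 0.96])
        sxy = np.sum((co - co.mean()) * (q - q.mean()))
        sxx = np.sum((co - co.mean()) ** 2)
        slope, intercept = co_flow_map()
        assert slope == pytest.approx(sxy / sxx, abs=1e-12)
        assert intercept == pytest.approx(q.mean() - sxy / sxx * co.mean(),
                                          abs=1e-12)


class TestPeakDataset:
    def test_default_factorial_has_330_points(self, truth_default):
        ds = generate_peak_dataset(SyntheticConfig(seed=0), truth_default)
        assert ds.n_points == 11 * 3 * 10 == 330
        assert len(ds.valves) == 11

    def test_noise_free_points_lie_on_the_sigmoid(self, full_noise_free_dataset,
                                                  truth_noise_free):
        pts = full_noise_free_dataset.points
        expected = sigmoid_ava(pts["q_peak_idx_mps"], pts["s"],
                               truth_noise_free.params)
        np.testing.assert_allclose(pts["ava_peak_frac"], expected, atol=1e-12)

    def test_seed_determinism(self, truth_default):
        a = generate_peak_dataset(SyntheticConfig(seed=11), truth_default)
        b = generate_peak_dataset(SyntheticConfig(seed=11), truth_default)
        c = generate_peak_dataset(SyntheticConfig(seed=12), truth_default)
        pd.testing.assert_frame_equal(a.points, b.points)
        assert not np.allclose(a.points["ava_peak_frac"],
                               c.points["ava_peak_frac"])

    def test_invalid_config_signalled(self):
        with pytest.raises(ValueError):
            SyntheticConfig(cardiac_outputs=())
        with pytest.raises(ValueError):
            SyntheticConfig(cardiac_outputs=(2.0, 1.0))
        with pytest.raises(ValueError):
            SyntheticConfig(n_valves=1)
        with pytest.raises(ValueError):
            SyntheticConfig(sampling_rate_daq=20000, sampling_rate_camera=1500)


class TestInjectMissing:
    def test_zero_missing_is_identity(self, full_noise_free_dataset):
        out = inject_missing(full_noise_free_dataset, 0, seed=1)
        pd.testing.assert_frame_equal(out.points,
                                      full_noise_free_dataset.points)

    def test_four_missing_leaves_326(self, full_noise_free_dataset):
        out = inject_missing(full_noise_free_dataset, 4, seed=5)
        assert out.n_points == 326

    def test_removing_everything_rejected(self, full_noise_free_dataset):
        with pytest.raises(ValueError):
            inject_missing(full_noise_free_dataset, 330, seed=0)

    def test_stripping_a_whole_valve_rejected(self):
        pts = pd.DataFrame({
            "valve_id": ["A", "A", "A", "B"],
            "grade": ["a"] * 4, "co_lpm": [1.0, 2.0, 3.0, 1.0],
            "q_peak_idx_mps": [0.3] * 4, "q_peak_mlps": [150.0] * 4,
            "ava_peak_frac": [0.2] * 4, "s": [1.0] * 4,
        })
        from avaflow import ValveDataset
        ds = ValveDataset(points=pts)
        raised = 0
        for seed in range(30):  # any 3-of-4 removal strips A or B
            try:
                inject_missing(ds, 3, seed=seed)
            except ValueError:
                raised += 1
        assert raised == 30


class TestRecordings:
    def test_cycle_volume_matches_cardiac_output(self, small_recordings,
                                                 small_config):
        # forward transvalvular volume per beat x heart rate ~ CO setpoint
        for rec in small_recordings:
            q_inst = compute_q_inst(rec.channels["pump_position"],
                                    rec.piston_area_cm2,
                                    rec.channels["q_retro"], rec.daq_rate)
            fwd_ml = np.trapezoid(np.clip(q_inst, 0, None),
                                  dx=1.0 / rec.daq_rate) / small_config.n_beats
            co = fwd_ml * rec.hr_bpm / 1000.0
            assert co == pytest.approx(rec.co_lpm, rel=0.01)

    def test_afterload_targets_met(self, small_recordings, small_config):
        for rec in small_recordings:
            p_ao = rec.channels["p_ao"]
            assert p_ao.max() == pytest.approx(small_config.systolic_mmhg,
                                               abs=2.0)
            assert p_ao.min() == pytest.approx(small_config.diastolic_mmhg,
                                               abs=2.0)

    def test_zero_retro_amplitude_means_pump_flow_is_transvalvular(
            self, truth_noise_free):
        cfg = SyntheticConfig(seed=2, n_valves=2, grades=("a",),
                              cardiac_outputs=(2.5,), retro_frac=0.0,
                              delays_ms={})
        rec = generate_recordings(cfg, truth_noise_free)[0]
        q_inst = compute_q_inst(rec.channels["pump_position"],
                                rec.piston_area_cm2,
                                rec.channels["q_retro"], rec.daq_rate)
        # with no retrograde leak, subtracting the mitral-probe flow leaves
        # the transvalvular flow everywhere (incl. zero flow in diastole)
        q_tv = rec.channels["q_pump"] - rec.channels["q_retro"]
        interior = slice(2, -2)  # gradient endpoints are one-sided
        np.testing.assert_allclose(q_inst[interior], q_tv[interior], atol=0.5)
        assert np.all(q_tv >= -1e-9)

    def test_retro_notch_dips_transvalvular_flow(self, small_recordings):
        rec = small_recordings[0]
        q_tv = rec.channels["q_pump"] - rec.channels["q_retro"]
        # a notch: local minimum strictly inside the rising ejection phase
        beat = q_tv[:int(rec.daq_rate * 60 / rec.hr_bpm)]
        peak = np.argmax(beat)
        onset = np.argmax(beat > 0.02 * beat.max())
        rising = beat[onset:peak]
        assert np.any(np.diff(rising) < 0)

    def test_camera_lead_is_exact_by_construction(self, truth_noise_free):
        base = dict(seed=4, n_valves=2, grades=("a",), cardiac_outputs=(2.5,))
        rec0 = generate_recordings(SyntheticConfig(**base, delays_ms={}),
                                   truth_noise_free)[0]
        rec1 = generate_recordings(
            SyntheticConfig(**base, delays_ms={"ava": 14.0}),
            truth_noise_free)[0]
        shift = int(round(14e-3 * rec1.camera_rate))
        np.testing.assert_array_equal(np.roll(rec1.ava_series, shift),
                                      rec0.ava_series)

    def test_recordings_deterministic(self, truth_noise_free):
        cfg = SyntheticConfig(seed=9, n_valves=2, grades=("a",),
                              cardiac_outputs=(5.0,))
        a = generate_recordings(cfg, truth_noise_free)[0]
        b = generate_recordings(cfg, truth_noise_free)[0]
        np.testing.assert_array_equal(a.ava_series, b.ava_series)
        np.testing.assert_array_equal(a.channels["p_lv"], b.channels["p_lv"])

    def test_gradient_grows_with_stiffness(self, small_recordings):
        by = {(r.valve_id, r.grade, r.co_lpm): r for r in small_recordings}
        a = by[("V01", "a", 5.0)]
        c = by[("V01", "c", 5.0)]
        dp_a = (a.channels["p_lv"] - a.channels["p_ao"]).max()
        dp_c = (c.channels["p_lv"] - c.channels["p_ao"]).max()
        assert dp_c > dp_a
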