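"""Generator checks: phase structure, modality consistency, determinism."""

import numpy as np
import pytest

import cmjkit as ck
from cmjkit.synthetic import GRID_RATE, IMAGE_ORIGIN_PX


def flight_runs(labels):
    fl = (labels == "flight").astype(int)
    d = np.diff(fl)
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    return list(zip(starts, stops))


class TestSimulateMotion:
    def test_flight_duration_matches_ballistics(self, clean_motion):
        # 19.62 cm <-> 0.400 s is the exact inversion of h = 100 g Tf^2 / 8
        runs = flight_runs(clean_motion.phase_labels)
        for a, b in runs:
            assert (b - a) / GRID_RATE == pytest.approx(0.400, abs=1.5 / GRID_RATE)

    def test_force_zero_in_flight_and_freefall_com(self, clean_motion):
        fl = clean_motion.phase_labels == "flight"
        assert np.all(clean_motion.vertical_force[fl] == 0.0)
        # COM follows d0 + v0 t - g t^2 / 2 during flight: second difference
        # of position equals -g dt^2 exactly
        a, b = flight_runs(clean_motion.phase_labels)[0]
        z = clean_motion.com_height[a:b]
        acc = np.diff(z, 2) * GRID_RATE**2
        assert np.allclose(acc, -9.81, atol=1e-6)

    def test_toe_apex_equals_true_height(self, clean_motion, clean_spec):
        baseline = clean_spec.toe_baseline_m
        apex_cm = (clean_motion.toe_height.max() - baseline) * 100
        assert apex_cm == pytest.approx(clean_spec.true_height, abs=1e-4)

    def test_zero_height_limit_has_no_flight(self):
        spec = ck.JumpSpec(true_height=0.0, countermovement_depth=25.0, seed=2)
        m = ck.simulate_motion(spec)
        assert set(np.unique(m.phase_labels)) <= {"stance", "countermovement",
                                                  "propulsion"}

    def test_three_reps_separated_by_rest(self):
        spec = ck.JumpSpec(true_height=22.0, n_reps=3, rest_between_reps=1.0, seed=3)
        m = ck.simulate_motion(spec)
        runs = flight_runs(m.phase_labels)
        assert len(runs) == 3
        gaps = [(runs[i + 1][0] - runs[i][1]) / GRID_RATE for i in range(2)]
        assert all(g >= spec.rest_between_reps for g in gaps)

    def test_force_phase_consistency(self, clean_motion, clean_spec):
        bw = clean_spec.body_mass * 9.81
        lab, f = clean_motion.phase_labels, clean_motion.vertical_force
        assert np.mean(f[lab == "stance"]) == pytest.approx(bw, rel=1e-9)
        assert f[lab == "countermovement"].min() < 0.95 * bw
        assert f[lab == "propulsion"].max() > 1.05 * bw
        assert f[lab == "landing"].max() > 1.05 * bw

    @pytest.mark.parametrize("field,value", [("true_height", -1.0),
                                             ("body_mass", 0.0),
                                             ("n_reps", 0),
                                             ("scale_R_true", -3.0),
                                             ("spike_prob", 1.5)])
    def test_invalid_spec_rejected(self, field, value):
        spec = ck.JumpSpec(**{field: value})
        with pytest.raises(ValueError):
            ck.simulate_motion(spec)


class TestRenderForcePlate:
    def test_noise_free_flight_exactly_zero(self, clean_motion, clean_spec):
        f = ck.render_force_plate(clean_motion, clean_spec)
        fl = clean_motion.phase_labels[::GRID_RATE // 1000] == "flight"
        assert np.all(f.values[fl] == 0.0)

    def test_flight_noise_sd_matches_spec(self):
        spec = ck.JumpSpec(true_height=20.0, force_noise_sd=2.0, seed=4)
        m = ck.simulate_motion(spec)
        f = ck.render_force_plate(m, spec)
        fl = m.phase_labels[::GRID_RATE // 1000] == "flight"
        assert fl.sum() >= 400
        assert np.std(f.values[fl]) == pytest.approx(2.0, rel=0.2)

    def test_stance_mean_is_bodyweight(self, clean_motion, clean_spec):
        f = ck.render_force_plate(clean_motion, clean_spec)
        st = clean_motion.phase_labels[::GRID_RATE // 1000] == "stance"
        assert np.mean(f.values[st]) == pytest.approx(
            clean_spec.body_mass * 9.81, rel=0.01)


class TestRenderOmc:
    def test_noise_free_toe_apex_mm(self, clean_recording, clean_spec):
        toe = clean_recording.omc.toe.values
        baseline = clean_spec.toe_baseline_m * 1000
        # up to 1/2 sample of apex quantisation at 100 Hz
        assert toe.max() - baseline == pytest.approx(
            clean_spec.true_height * 10, abs=0.2)

    def test_dropout_produces_zero_run(self):
        spec = ck.JumpSpec(true_height=20.0, seed=5)
        omc = ck.render_omc(ck.simulate_motion(spec), spec, dropout=True)
        assert np.any(omc.hip.values == 0.0)
        assert np.any(omc.toe.values == 0.0)

    def test_hip_apex_time_matches_motion(self, clean_recording, clean_motion):
        hip = clean_recording.omc.hip
        t_apex = hip.times[np.argmax(hip.values)]
        assert abs(t_apex - clean_motion.apex_times()[0]) <= 1 / 100 + 1e-9


class TestRenderMmc:
    def test_noise_free_affine_inversion(self, clean_recording, clean_spec, clean_motion):
        hip_mm = (IMAGE_ORIGIN_PX - clean_recording.mmc.hip.values) * clean_spec.scale_R_true
        truth = clean_motion.hip_height[::GRID_RATE // 30] * 1000
        assert np.allclose(hip_mm, truth, atol=1e-9)

    def test_spike_count_seeded_and_plausible(self):
        spec = ck.JumpSpec(true_height=20.0, spike_prob=0.02, stance_duration=4.0,
                           rest_between_reps=4.0, seed=6)
        mmc1 = ck.render_mmc(ck.simulate_motion(spec), spec)
        mmc2 = ck.render_mmc(ck.simulate_motion(spec), spec)
        assert np.array_equal(mmc1.hip.values, mmc2.hip.values)  # reproducible
        n = len(mmc1.hip)
        spikes = (mmc1.confidence.values < 0.3).sum()
        assert 0 < spikes < 3 * 0.02 * n  # near n * p, loose binomial bound

    def test_determinism_across_full_recording(self):
        spec = ck.JumpSpec(true_height=23.0, spike_prob=0.01, seed=42)
        r1, r2 = ck.simulate_recording(spec), ck.simulate_recording(spec)
        assert np.array_equal(r1.force.values, r2.force.values)
        assert np.array_equal(r1.omc.toe.values, r2.omc.toe.values)
        assert np.array_equal(r1.mmc.hip.values, r2.mmc.hip.values)
        assert np.array_equal(r1.mmc.confidence.values, r2.mmc.confidence.values)

    def test_modalities_share_one_motion(self, clean_recording):
        """First-rep apex times of the renderings agree within one 30 fps
        frame, and the first force-plate zero interval brackets them."""
        rec = clean_recording
        t_apex = rec.motion.apex_times()[0]
        first = slice(0, int(3.0 * 100)), slice(0, int(3.0 * 30))
        hip_omc = rec.omc.hip.values[first[0]]
        hip_mmc = rec.mmc.hip.values[first[1]]
        t_omc = np.argmax(hip_omc) / 100.0
        t_mmc = np.argmin(hip_mmc) / 30.0  # image y grows downward
        assert abs(t_omc - t_apex) <= 1 / 30 + 1e-9
        assert abs(t_mmc - t_apex) <= 1 / 30 + 1e-9
        zeros = np.flatnonzero(rec.force.values[:3000] == 0.0) / 1000.0
        assert zeros.min() < t_apex < zeros.max()
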