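import dataclasses
import logging

import numpy as np
import pytest
from scipy import stats

from thalattn.behavior_metrics import lick_index
from thalattn.synthetic_session import (
    BehaviorParams,
    PopulationParams,
    UnitGroundTruth,
    read_session,
    simulate_behavior,
    simulate_population,
    simulate_spikes,
    spike_rate_vector,
    write_session,
)
from thalattn.task_design import draw_full_schedule, draw_shaping_schedule


def _plain_unit(**kw):
    base = dict(unit_id="u", baseline_rate=5.0, region="POm",
                position=(-2.0, 3.3, 1.5))
    base.update(kw)
    return UnitGroundTruth(**base)


class TestSpikeGenerator:
    def test_homogeneous_rate_matches_baseline(self):
        sched = draw_full_schedule(20, seed=1)
        spk = simulate_spikes(sched, _plain_unit(), None, seed=2)
        est = spk.size / sched.session_length
        sem = np.sqrt(5.0 / sched.session_length)
        assert abs(est - 5.0) < 4 * sem

    def test_time_rescaling_yields_unit_exponential_intervals(self):
        sched = draw_full_schedule(20, seed=3)
        truth = _plain_unit(baseline_rate=8.0, gain_tactile=3.0,
                            offset_gain=2.0)
        spk = simulate_spikes(sched, truth, None, seed=4)
        rate = spike_rate_vector(sched, truth, None)
        cum = np.cumsum(rate) / 1000.0
        rescaled = np.diff(cum[(spk * 1000).astype(int)])
        p = stats.kstest(rescaled, "expon").pvalue
        assert p > 0.01

    def test_gain_window_respects_latency_and_duration(self):
        sched = draw_full_schedule(10, seed=5)
        truth = _plain_unit(gain_tactile=3.0, response_latency=0.1,
                            response_duration=0.5)
        rate = spike_rate_vector(sched, truth, None)
        on = sched.onsets("tactile")[0]
        i = int(on * 1000)
        assert rate[i + 50] == pytest.approx(5.0)     # before latency
        assert rate[i + 150] == pytest.approx(15.0)   # inside response
        assert rate[i + 700] == pytest.approx(5.0)    # after response

    def test_negative_rates_floored_with_warning(self, caplog):
        sched = draw_full_schedule(5, seed=6)
        behavior = simulate_behavior(sched, "tactile", "trained", seed=7)
        truth = _plain_unit(coupling={"pupil": -100.0, "whisk": 0.0,
                                      "lick": 0.0})
        with caplog.at_level(logging.WARNING, logger="thalattn.synthetic_session"):
            rate = spike_rate_vector(sched, truth, behavior)
        assert np.all(rate >= 0)
        assert any("floored" in r.message for r in caplog.records)

    def test_dead_time_enforced(self):
        sched = draw_full_schedule(10, seed=8)
        truth = _plain_unit(baseline_rate=50.0, dead_time_s=0.01)
        spk = simulate_spikes(sched, truth, None, seed=9)
        assert np.diff(spk).min() >= 0.01


class TestBehaviorSimulator:
    def test_whisker_trace_band_limited(self):
        sched = draw_full_schedule(15, seed=10)
        beh = simulate_behavior(sched, "tactile", "trained", seed=11)
        x = beh.whisker_angle.values - beh.whisker_angle.values.mean()
        spec = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(x.size, 1.0 / beh.whisker_angle.sample_rate)
        inside = spec[(freqs >= 2) & (freqs <= 40)].sum()
        assert inside / spec.sum() > 0.9

    def test_trained_mouse_anticipates_cs_plus(self):
        sched = draw_full_schedule(40, seed=12)
        beh = simulate_behavior(sched, "tactile", "trained", seed=13)
        lis = [lick_index(beh.lick_times, e).li for e in sched.events
               if e.modality == "tactile"]
        lis = [v for v in lis if v is not None]
        assert np.mean(lis) > 0.3

    def test_naive_mouse_ignores_both_stimuli(self):
        sched = draw_full_schedule(60, seed=14)
        beh = simulate_behavior(sched, "tactile", "naive", seed=15)
        for mod in ("tactile", "visual"):
            lis = [lick_index(beh.lick_times, e).li for e in sched.events
                   if e.modality == mod]
            lis = [v for v in lis if v is not None]
            assert abs(np.mean(lis)) < 0.2

    def test_shaped_visual_mouse_withholds_licking_during_puff(self):
        sched = draw_shaping_schedule(50, seed=16, cs_plus="visual")
        beh = simulate_behavior(sched, "visual", "shaped", seed=17)
        lis = [lick_index(beh.lick_times, e).li for e in sched.events
               if e.modality == "tactile"]
        lis = [v for v in lis if v is not None]
        assert np.mean(lis) < -0.2

    def test_traces_cover_session(self):
        sched = draw_full_schedule(10, seed=18)
        beh = simulate_behavior(sched, "visual", "trained", seed=19)
        for tr in (beh.pupil, beh.whisker_angle):
            assert tr.end_time >= sched.session_length - 1.0 / tr.sample_rate


class TestPopulation:
    def test_visual_cohort_ml_gradient_has_injected_sign(self):
        sess = simulate_population(
            120, "visual", seed=20,
            params=PopulationParams(n_per_modality=5))
        resp = [u for u in sess.units
                if u.gain_tactile != 1.0 or u.gain_visual != 1.0]
        ml = np.array([u.position[2] for u in resp])
        diff = np.array([u.gain_tactile - u.gain_visual for u in resp])
        assert np.corrcoef(ml, diff)[0, 1] > 0.5

    def test_single_unit_session_runs(self):
        sess = simulate_population(1, "tactile", seed=21,
                                   params=PopulationParams(n_per_modality=5))
        assert len(sess.units) == 1
        assert set(sess.spikes) == {sess.units[0].unit_id}

    def test_ground_truth_roundtrips_through_bundle(self, tmp_path):
        sess = simulate_population(3, "visual", seed=22,
                                   params=PopulationParams(n_per_modality=8))
        write_session(sess, tmp_path / "bundle")
        back = read_session(tmp_path / "bundle")
        assert back.units == sess.units
        assert back.cohort == sess.cohort
        assert back.seed == sess.seed
        assert back.population_params == sess.population_params
        assert dataclasses.asdict(back.behavior.params) == dataclasses.asdict(
            sess.behavior.params)
        assert back.schedule.events == sess.schedule.events
        assert np.allclose(back.behavior.lick_times, sess.behavior.lick_times,
                           atol=1e-4)
        for uid in sess.spikes:
            assert np.allclose(back.spikes[uid], sess.spikes[uid], atol=1e-3)

    def test_invalid_args_rejected(self):
        with pytest.raises(ValueError):
            simulate_population(0, "tactile", seed=1)
        with pytest.raises(ValueError):
            simulate_behavior(draw_full_schedule(2, seed=1), "auditory",
                              "trained", seed=1)
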