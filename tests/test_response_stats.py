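import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from thalattn.response_stats import (
    CROSS_MODAL_EXCLUSION_S,
    build_trial_windows,
    classify_responses,
    offset_period_analysis,
    position_selectivity_model,
    response_latency,
    retained_presentations,
    selectivity_index,
)
from thalattn.synthetic_session import UnitGroundTruth, simulate_spikes
from thalattn.task_design import (
    StimulusEvent,
    StimulusSchedule,
    draw_full_schedule,
)


def _schedule_from_onsets(tactile, visual):
    events = [StimulusEvent(t, "tactile", rewarded=True) for t in tactile]
    events += [StimulusEvent(t, "visual", rewarded=False) for t in visual]
    end = max(e.offset_time for e in events) + 10.0
    return StimulusSchedule(events=events, session_length=end,
                            task_phase="full", cs_plus="tactile")


class TestOverlapExclusion:
    def test_close_cross_modal_pair_both_dropped(self):
        sched = _schedule_from_onsets([100.0], [103.0])
        assert retained_presentations(sched) == []

    def test_distant_pair_both_retained(self):
        sched = _schedule_from_onsets([100.0], [110.0])
        assert len(retained_presentations(sched)) == 2

    def test_matches_bruteforce_double_loop(self, rng):
        for seed in range(10):
            sched = draw_full_schedule(12, seed=seed)
            kept = retained_presentations(sched)
            expect = []
            for e in sched.events:
                drop = False
                for o in sched.events:
                    if (o.modality != e.modality
                            and abs(o.onset_time - e.onset_time)
                            <= CROSS_MODAL_EXCLUSION_S):
                        drop = True
                expect.append((e, drop))
            assert kept == [e for e, drop in expect if not drop]

    def test_window_counts_on_known_spikes(self):
        sched = _schedule_from_onsets([100.0], [120.0])
        # 3 spikes in the baseline window, 5 in the stimulus window,
        # 2 in the offset window; one at onset lands in the ambiguity band
        spk = np.array([99.2, 99.4, 99.6, 100.0,
                        100.2, 100.3, 100.5, 100.7, 100.9,
                        102.5, 103.9])
        df = build_trial_windows(spk, sched)
        row = df[df.modality == "tactile"].iloc[0]
        assert row.baseline_count == 3
        assert row.stimulus_count == 5
        assert row.offset_count == 2
        assert row.baseline_rate == pytest.approx(3 / 0.95)
        assert row.offset_rate == pytest.approx(1.0)


class TestSelectivityIndex:
    @pytest.mark.parametrize("frb,fra,frv,expected", [
        (2.0, 10.0, 2.0, 1.0),
        (2.0, 6.0, 6.0, 0.0),
        (2.0, 2.0, 10.0, -1.0),
    ])
    def test_worked_examples(self, frb, fra, frv, expected):
        assert selectivity_index(frb, fra, frv) == expected

    def test_undefined_when_no_deviation(self):
        assert selectivity_index(5.0, 5.0, 5.0) is None

    @given(frb=st.floats(0.0, 50.0), fra=st.floats(0.0, 50.0),
           frv=st.floats(0.0, 50.0))
    def test_antisymmetric_under_modality_swap(self, frb, fra, frv):
        si = selectivity_index(frb, fra, frv)
        swapped = selectivity_index(frb, frv, fra)
        if si is None:
            assert swapped is None
        else:
            assert swapped == pytest.approx(-si)

    @given(frb=st.floats(0.1, 20.0), fra=st.floats(0.1, 20.0),
           frv=st.floats(0.1, 20.0), scale=st.floats(0.01, 100.0))
    def test_invariant_to_common_rate_rescaling(self, frb, fra, frv, scale):
        si = selectivity_index(frb, fra, frv)
        scaled = selectivity_index(scale * frb, scale * fra, scale * frv)
        if si is None:
            assert scaled is None
        else:
            assert scaled == pytest.approx(si, abs=1e-9)

    def test_nonfinite_rates_rejected(self):
        with pytest.raises(ValueError):
            selectivity_index(np.nan, 1.0, 1.0)


class TestClassification:
    @pytest.mark.parametrize("gain_t,gain_v,expected", [
        (3.0, 1.0, "puff"),
        (3.0, 3.0, "both"),
        (1.0, 3.0, "grating"),
    ])
    def test_strong_gain_units_labelled(self, gain_t, gain_v, expected):
        sched = draw_full_schedule(80, seed=31)
        truth = UnitGroundTruth(
            unit_id="u", baseline_rate=8.0, region="POm",
            position=(-2.0, 3.3, 1.5), gain_tactile=gain_t,
            gain_visual=gain_v, response_latency=0.05,
            response_duration=1.5)
        spk = simulate_spikes(sched, truth, None, seed=32)
        res = classify_responses({"u": build_trial_windows(spk, sched)})
        assert res.loc["u", "significant"]
        assert res.loc["u", "label"] == expected

    def test_constant_count_unit_untestable(self):
        sched = _schedule_from_onsets([100.0, 130.0], [115.0, 145.0])
        res = classify_responses({"u": build_trial_windows(np.empty(0), sched)})
        assert not res.loc["u", "testable"]
        assert not res.loc["u", "significant"]
        assert res.loc["u", "label"] == "none"

    def test_alpha_one_degenerate_threshold_flags_null_unit(self, rng):
        # With a family of one, Holm at alpha = 1 accepts any p value, so
        # even a stimulus-free unit is flagged responsive.
        sched = draw_full_schedule(20, seed=33)
        spk = np.sort(rng.uniform(0, sched.session_length,
                                  int(5 * sched.session_length)))
        res = classify_responses({"u0": build_trial_windows(spk, sched)},
                                 alpha=1.0)
        assert res.loc["u0", "testable"]
        assert res.loc["u0", "significant"]


class TestLatency:
    def _unit_spikes(self, sched, latency, gain=4.0, seed=0):
        truth = UnitGroundTruth(
            unit_id="u", baseline_rate=10.0, region="POm",
            position=(-2.0, 3.3, 1.5), gain_tactile=gain,
            response_latency=latency, response_duration=1.0)
        return simulate_spikes(sched, truth, None, seed=seed)

    def test_injected_step_recovered_within_a_bin(self):
        sched = draw_full_schedule(100, seed=41)
        onsets = sched.onsets("tactile")
        spk = self._unit_spikes(sched, 0.12, seed=42)
        est = response_latency(spk, onsets)
        assert est is not None
        assert abs(est - 0.12) <= 0.01

    def test_flat_unit_returns_none(self):
        sched = draw_full_schedule(50, seed=43)
        spk = self._unit_spikes(sched, 0.1, gain=1.0, seed=44)
        assert response_latency(spk, sched.onsets("tactile")) is None

    def test_single_bin_transient_rejected(self, rng):
        onsets = 5.0 + 12.0 * np.arange(100)
        spk = np.sort(rng.uniform(0, onsets[-1] + 10, 12000))
        # one extra burst confined to a single 10-ms bin each trial
        burst = np.concatenate([on + 0.200 + rng.uniform(0, 0.01, 3)
                                for on in onsets])
        spk = np.sort(np.concatenate([spk, burst]))
        est = response_latency(spk, onsets, min_run=2)
        # with min_run=1 the transient is found, proving it is the run
        # requirement (not a missing response) that rejects it
        assert response_latency(spk, onsets, min_run=1) == pytest.approx(0.2)
        assert est is None

    def test_invariant_to_added_constant_rate(self, rng):
        sched = draw_full_schedule(100, seed=45)
        onsets = sched.onsets("tactile")
        spk = self._unit_spikes(sched, 0.15, seed=46)
        extra = np.sort(rng.uniform(0, sched.session_length,
                                    int(20 * sched.session_length)))
        merged = np.sort(np.concatenate([spk, extra]))
        a = response_latency(spk, onsets)
        b = response_latency(merged, onsets)
        assert a is not None and b is not None
        assert abs(a - b) <= 0.02

    def test_too_few_presentations_rejected(self):
        with pytest.raises(ValueError):
            response_latency(np.arange(100.0), np.arange(5.0))


class TestOffsetAnalysis:
    def _windows(self, offset_gain, seed, n=40):
        sched = draw_full_schedule(n, seed=seed)
        out = {}
        for i in range(12):
            truth = UnitGroundTruth(
                unit_id=f"u{i}", baseline_rate=8.0, region="POm",
                position=(-2.0, 3.3, 1.5), offset_gain=offset_gain)
            spk = simulate_spikes(sched, truth, None, seed=seed + 100 + i)
            out[f"u{i}"] = build_trial_windows(spk, sched)
        return out

    def test_cs_plus_offset_elevation_detected(self):
        report = offset_period_analysis(
            {"tactile": self._windows(offset_gain=2.5, seed=51)})
        within = report["within_cohort"]["tactile"]
        assert within["offset_vs_zero_tactile_p"] < 0.01
        assert within["offset_puff_vs_grating_p"] < 0.01

    def test_identical_cohorts_show_no_interaction(self):
        w = self._windows(offset_gain=2.0, seed=52)
        report = offset_period_analysis({"tactile": w, "visual": w})
        assert report["anova"]["d_offset"]["cohort_p"] > 0.5
        assert report["anova"]["d_offset"]["interaction_p"] > 0.5


class TestPositionModel:
    def _records(self, rng, slope, n=150):
        rows = []
        for cohort in ("tactile", "visual"):
            for _ in range(n):
                ap, dv, ml = rng.uniform([-2.5, 2.9, 1.0], [-1.5, 3.8, 2.0])
                si = 0.8 if cohort == "tactile" else slope * (ml - 1.5)
                rows.append({
                    "si": float(np.clip(si + rng.normal(0, 0.15), -1, 1)),
                    "AP": ap, "DV": dv, "ML": ml, "cohort": cohort})
        return pd.DataFrame(rows)

    def test_injected_interaction_recovered_with_sign(self, rng):
        fit = position_selectivity_model(self._records(rng, slope=1.0))
        term = "C(cohort)[T.visual]:ML"
        assert fit.pvalues[term] < 0.001
        assert fit.params[term] > 0
        assert fit.adjusted_r2 > 0.2

    def test_degenerate_positions_rejected(self, rng):
        df = self._records(rng, slope=0.5)
        df[["AP", "DV", "ML"]] = 1.0
        with pytest.raises(ValueError):
            position_selectivity_model(df)

    def test_minimum_unit_count_enforced(self, rng):
        with pytest.raises(ValueError):
            position_selectivity_model(self._records(rng, 1.0, n=5))
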