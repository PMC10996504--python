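"""Parameter-recovery and error-control simulations.

Each function here generates synthetic data with known ground truth, runs
the corresponding analysis stage, and reports how well the truth is
recovered (or how well error rates are controlled on null data). They
back the `thalattn recover` command and the validation suite.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from . import behavior_metrics, movement_model, physio_signals, response_stats
from .synthetic_session import (
    PopulationParams,
    UnitGroundTruth,
    _draw_unit,
    simulate_behavior,
    simulate_spikes,
)
from .task_design import (
    StimulusEvent,
    StimulusSchedule,
    draw_full_isis,
    draw_full_schedule,
    hazard_rate,
)
from .unit_qc import DEFAULT_ATLAS, passes_refractory_qc


def isi_schedule_stats(seed: int, n: int = 300_000,
                       flat_range_s: tuple[float, float] = (13.0, 45.0)) -> dict:
    """Sample statistics of the full-task ISI generator.

    Returns the sample mean and max of the drawn ISIs (seconds) and the
    max/min ratio of the empirical hazard over the flat range, where the
    shifted-exponential hazard is analytically constant at
    1 - exp(-1/10) per 1-s bin.
    """
    rng = np.random.default_rng(seed)
    isis = draw_full_isis(n, rng)
    hc = hazard_rate(isis, bin_width=1.0)
    centers = hc.bin_edges[:-1] + 0.5
    sel = (centers >= flat_range_s[0]) & (centers < flat_range_s[1]) & hc.defined()
    h = hc.hazard[sel]
    return {
        "n": n,
        "mean_isi_s": float(isis.mean()),
        "max_isi_s": float(isis.max()),
        "min_isi_s": float(isis.min()),
        "hazard_max_min_ratio": float(h.max() / h.min()),
        "hazard_mean": float(h.mean()),
    }


def si_worked_examples() -> dict:
    """The three printed selectivity-index configurations."""
    return {
        "puff_only": response_stats.selectivity_index(2.0, 10.0, 2.0),
        "equal_magnitude": response_stats.selectivity_index(2.0, 6.0, 6.0),
        "grating_only": response_stats.selectivity_index(2.0, 2.0, 10.0),
    }


def _li_from_counts(n_stim: int, n_base: int) -> float | None:
    """Lick index for given window counts, via the real windowing code."""
    stim = StimulusEvent(10.0, "tactile", rewarded=True)
    licks = np.concatenate([
        np.linspace(10.2, 11.8, n_stim) if n_stim else np.empty(0),
        np.linspace(8.2, 9.8, n_base) if n_base else np.empty(0),
    ])
    return behavior_metrics.lick_index(licks, stim).li


def lick_index_checks(seed: int, n_pairs: int = 1000) -> dict:
    """Equal-count LI and the antisymmetry property over random counts."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_pairs):
        a, b = int(rng.integers(0, 20)), int(rng.integers(0, 20))
        if a + b == 0:
            continue
        worst = max(worst, abs(_li_from_counts(a, b) + _li_from_counts(b, a)))
    return {
        "li_equal_counts": _li_from_counts(3, 3),
        "max_antisymmetry_error": worst,
        "n_pairs": n_pairs,
    }


def _single_modality_schedule(n_trials: int, spacing_s: float = 12.0,
                              modality: str = "tactile") -> StimulusSchedule:
    events = [
        StimulusEvent(5.0 + i * spacing_s, modality, rewarded=True)
        for i in range(n_trials)
    ]
    return StimulusSchedule(
        events=events,
        session_length=events[-1].offset_time + 5.0,
        task_phase="full",
        cs_plus=modality,
    )


def latency_recovery(seed: int, n_units: int = 50, n_trials: int = 100) -> dict:
    """Recover injected response latencies with the PSTH latency detector."""
    rng = np.random.default_rng(seed)
    schedule = _single_modality_schedule(n_trials)
    onsets = schedule.onsets("tactile")
    errors = []
    n_none = 0
    for i in range(n_units):
        true_lat = float(rng.uniform(0.02, 0.30))
        truth = UnitGroundTruth(
            unit_id=f"lat{i}", baseline_rate=10.0, region="POm",
            position=(-2.0, 3.3, 1.5), gain_tactile=4.0,
            response_latency=true_lat, response_duration=1.0)
        spk = simulate_spikes(schedule, truth, None,
                              seed=int(rng.integers(2**31)))
        est = response_stats.response_latency(spk, onsets)
        if est is None:
            n_none += 1
        else:
            errors.append(abs(est - true_lat))
    flat = UnitGroundTruth(
        unit_id="flat", baseline_rate=10.0, region="POm",
        position=(-2.0, 3.3, 1.5))
    flat_spk = simulate_spikes(schedule, flat, None,
                               seed=int(rng.integers(2**31)))
    return {
        "n_units": n_units,
        "n_detected": len(errors),
        "n_missed": n_none,
        "median_abs_error_ms": float(np.median(errors) * 1000.0),
        "flat_unit_latency": response_stats.response_latency(flat_spk, onsets),
    }


def null_classification_fwer(seed: int, n_units: int = 200,
                             n_trials: int = 100, alpha: float = 0.05) -> dict:
    """Family-wise false-positive control on gain-free (null) units."""
    rng = np.random.default_rng(seed)
    schedule = draw_full_schedule(n_trials, seed=int(rng.integers(2**31)))
    windows = {}
    for i in range(n_units):
        truth = UnitGroundTruth(
            unit_id=f"null{i}", region="POm", position=(-2.0, 3.3, 1.5),
            baseline_rate=float(np.exp(rng.uniform(np.log(2.0), np.log(20.0)))))
        spk = simulate_spikes(schedule, truth, None,
                              seed=int(rng.integers(2**31)))
        windows[truth.unit_id] = response_stats.build_trial_windows(spk, schedule)
    res = response_stats.classify_responses(windows, alpha=alpha)
    return {
        "n_units": n_units,
        "n_significant": int(res.significant.sum()),
        "false_positive_fraction": float(res.significant.mean()),
    }


def _window_effect(series: np.ndarray, binned, onsets) -> float:
    """Mean (stimulus-window minus baseline-window) value of a bin series
    across trials, windows of 1 s each side of onset."""
    psth = movement_model.event_aligned_series(series, binned, onsets,
                                               window_s=(-1.0, 1.0))
    pre = psth.mean[psth.time_rel < 0]
    post = psth.mean[psth.time_rel >= 0]
    return float(post.mean() - pre.mean())


def movement_dissociation(seed: int, n_pairs: int = 50,
                          n_per_modality: int = 60) -> dict:
    """Movement regression separates coupling-driven from gain-driven units.

    Coupling-only units fire more during the air puff solely because
    whisking (which they are coupled to) is puff-evoked; gain units carry a
    direct stimulus response. After regressing out movement, the residual
    stimulus effect should collapse for the former and survive for the
    latter (paired sign test across units).
    """
    rng = np.random.default_rng(seed)
    schedule = draw_full_schedule(n_per_modality, seed=int(rng.integers(2**31)),
                                  cs_plus="tactile")
    behavior = simulate_behavior(schedule, "tactile", "trained",
                                 seed=int(rng.integers(2**31)))
    # Analysis-side predictors: re-estimated whisking amplitude, cleaned pupil.
    amp = physio_signals.whisk_amplitude(behavior.whisker_angle).amplitude
    pupil = physio_signals.clean_pupil_trace(behavior.pupil)
    spikes = {}
    for i in range(n_pairs):
        cpl = UnitGroundTruth(
            unit_id=f"cpl{i}", baseline_rate=10.0, region="POm",
            position=(-2.0, 3.3, 1.5),
            coupling={"pupil": 0.0, "whisk": 0.6, "lick": 0.0})
        gain = UnitGroundTruth(
            unit_id=f"gain{i}", baseline_rate=10.0, region="POm",
            position=(-2.0, 3.3, 1.5), gain_tactile=3.0,
            response_latency=0.05, response_duration=1.5)
        spikes[cpl.unit_id] = simulate_spikes(schedule, cpl, behavior,
                                              seed=int(rng.integers(2**31)))
        spikes[gain.unit_id] = simulate_spikes(schedule, gain, behavior,
                                               seed=int(rng.integers(2**31)))
    binned = movement_model.bin_session(
        schedule.session_length, spikes, behavior.lick_times,
        {"whisk": amp, "pupil": pupil})
    onsets = np.array([e.onset_time for e in
                       response_stats.retained_presentations(schedule)
                       if e.modality == "tactile"])
    raw_cpl, resid_cpl, resid_gain = [], [], []
    for i in range(n_pairs):
        for uid, store_raw, store_resid in (
                (f"cpl{i}", raw_cpl, resid_cpl), (f"gain{i}", None, resid_gain)):
            fit = movement_model.fit_movement_model(binned, uid)
            if store_raw is not None:
                store_raw.append(_window_effect(binned.rates[uid], binned, onsets))
            store_resid.append(_window_effect(fit.residuals, binned, onsets))
    resid_cpl = np.array(resid_cpl)
    resid_gain = np.array(resid_gain)
    n_greater = int(np.sum(resid_gain > resid_cpl))
    sign_p = float(stats.binomtest(n_greater, n_pairs,
                                   alternative="greater").pvalue)
    return {
        "n_pairs": n_pairs,
        "median_raw_effect_coupling_hz": float(np.median(raw_cpl)),
        "median_residual_effect_coupling_hz": float(np.median(resid_cpl)),
        "median_residual_effect_gain_hz": float(np.median(resid_gain)),
        "n_gain_greater": n_greater,
        "sign_test_p": sign_p,
    }


def _expected_si(truth: UnitGroundTruth) -> float | None:
    """Selectivity index implied by a unit's ground-truth parameters.

    Uses the expected rate in the 0.05-1 s stimulus window: the gain is
    active for the part of the window covered by [latency, latency +
    duration], so FR = baseline * (1 + (gain - 1) * covered_fraction).
    """
    lo, hi = response_stats.AMBIGUITY_S, response_stats.STIMULUS_WINDOW_S
    cover = (min(hi, truth.response_latency + truth.response_duration)
             - max(lo, truth.response_latency))
    frac = max(cover, 0.0) / (hi - lo)
    b = truth.baseline_rate
    fr_a = b * (1.0 + (truth.gain_tactile - 1.0) * frac)
    fr_v = b * (1.0 + (truth.gain_visual - 1.0) * frac)
    return response_stats.selectivity_index(b, fr_a, fr_v)


def _si_records(rng: np.random.Generator, n_per_cohort: int, slope: float,
                noise_sd: float = 0.15) -> pd.DataFrame:
    params = replace(PopulationParams(), responsive_fraction=1.0,
                     ml_selectivity_slope=slope)
    rows = []
    for cohort in ("tactile", "visual"):
        for i in range(n_per_cohort):
            truth = _draw_unit(rng, f"{cohort}{i}", cohort, params,
                               DEFAULT_ATLAS)
            si = _expected_si(truth)
            if si is None:
                continue
            si = float(np.clip(si + rng.normal(0.0, noise_sd), -1.0, 1.0))
            ap, dv, ml = truth.position
            rows.append({"si": si, "AP": ap, "DV": dv, "ML": ml,
                         "cohort": cohort})
    return pd.DataFrame(rows)


def position_model_recovery(seed: int, n_runs: int = 100,
                            n_units: int = 300, slope: float = 2.0,
                            alpha: float = 0.05) -> dict:
    """Sign recovery of an injected ML x cohort interaction, plus the
    false-rejection rate of the same term under a zero-slope null."""
    rng = np.random.default_rng(seed)
    term = "C(cohort)[T.visual]:ML"
    n_recovered = 0
    n_null_rejected = 0
    for _ in range(n_runs):
        df = _si_records(rng, n_units // 2, slope)
        fit = response_stats.position_selectivity_model(df)
        if fit.pvalues[term] < alpha and np.sign(fit.params[term]) == np.sign(slope):
            n_recovered += 1
        null = _si_records(rng, n_units // 2, 0.0)
        if response_stats.position_selectivity_model(null).pvalues[term] < alpha:
            n_null_rejected += 1
    return {
        "n_runs": n_runs,
        "n_units": n_units,
        "sign_recovery_fraction": n_recovered / n_runs,
        "null_rejection_fraction": n_null_rejected / n_runs,
    }


def qc_boundary_checks() -> dict:
    """The strict >10% refractory-violation exclusion boundary."""

    def train(n_bad: int, n_isis: int = 100) -> np.ndarray:
        isis = np.array([0.002] * n_bad + [0.1] * (n_isis - n_bad))
        return np.concatenate([[0.0], np.cumsum(isis)])

    return {
        "excluded_at_11_of_100": not passes_refractory_qc(train(11)),
        "retained_at_10_of_100": passes_refractory_qc(train(10)),
    }


def run_recovery_suite(seed: int, fast: bool = False) -> dict:
    """Run every recovery/error-control simulation and flag pass/fail.

    ``fast`` shrinks the simulation sizes (with correspondingly wider
    tolerances noted in the report) for quick smoke runs.
    """
    scale = 0.2 if fast else 1.0
    report: dict = {"seed": seed, "fast": fast}

    s = isi_schedule_stats(seed, n=int(300_000 * scale))
    s["pass"] = bool(abs(s["mean_isi_s"] - 20.0) <= 0.5
                     and s["max_isi_s"] <= 55.0
                     and s["hazard_max_min_ratio"] < (1.5 if fast else 1.25))
    report["schedule_statistics"] = s

    s = si_worked_examples()
    s["pass"] = (s["puff_only"] == 1.0 and s["equal_magnitude"] == 0.0
                 and s["grating_only"] == -1.0)
    report["selectivity_worked_examples"] = s

    s = lick_index_checks(seed)
    s["pass"] = bool(s["li_equal_counts"] == 0.0
                     and s["max_antisymmetry_error"] < 1e-12)
    report["lick_index_properties"] = s

    s = latency_recovery(seed, n_units=max(int(50 * scale), 10))
    s["pass"] = bool(s["median_abs_error_ms"] <= 10.0
                     and s["flat_unit_latency"] is None)
    report["latency_recovery"] = s

    s = null_classification_fwer(seed, n_units=max(int(200 * scale), 40))
    s["pass"] = bool(s["false_positive_fraction"] <= 0.05)
    report["classification_error_control"] = s

    s = movement_dissociation(seed, n_pairs=max(int(50 * scale), 10))
    s["pass"] = bool(s["sign_test_p"] < 0.01)
    report["movement_correction_dissociation"] = s

    s = position_model_recovery(seed, n_runs=max(int(100 * scale), 20))
    # The null-rejection rate is a binomial estimate of a 5% type-I rate;
    # compare against its one-sided 99% sampling bound rather than the
    # point value.
    bound = float(stats.binom.ppf(0.99, s["n_runs"], 0.05)) / s["n_runs"]
    s["null_rejection_bound"] = bound
    s["pass"] = bool(s["sign_recovery_fraction"] >= 0.9
                     and s["null_rejection_fraction"] <= bound)
    report["position_model_recovery"] = s

    s = qc_boundary_checks()
    s["pass"] = bool(s["excluded_at_11_of_100"] and s["retained_at_10_of_100"])
    report["qc_boundary"] = s

    report["all_pass"] = all(v["pass"] for k, v in report.items()
                             if isinstance(v, dict))
    return report
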