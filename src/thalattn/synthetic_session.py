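"""Synthetic conditioning sessions with known ground truth.

Real sessions pair a stimulus schedule with per-unit thalamic spike trains
and continuous behavior (licking, pupil radius at 60 Hz, whisker mean angle
at 125 Hz). This module emulates that statistical structure so every
analysis stage can be validated against known parameters:

* **Licking** is an inhomogeneous Poisson process: a low baseline rate, an
  anticipatory elevation during the rewarded stimulus once the animal has
  learned, a consumption burst for 2 s after each reward, and (in the
  shaped state) suppression during the unrewarded stimulus.
* **Pupil radius** combines a slow drift, a transient constriction at
  grating onset, a dilation following the air puff, and — for visually
  conditioned animals that have learned — a delayed dilation after the
  grating.
* **Whisker angle** oscillates in the whisk band (~8 Hz) around a setpoint;
  its cycle amplitude increases at air-puff onset.
* **Spikes** are an inhomogeneous Poisson process generated by discrete
  thinning on a 1-ms grid: rate r(t) = baseline x gain(t) + coupling
  weights dotted with (lagged pupil, whisking amplitude, lick rate), each
  mean-centered, floored at zero. gain(t) applies from stimulus onset +
  latency for the response duration, and an offset gain covers the 2 s
  after the rewarded stimulus.

All generator parameters are recorded as ground truth for recovery tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from .physio_signals import FixedRateTrace, write_trace_csv, read_trace_csv
from .task_design import (
    StimulusSchedule,
    draw_full_schedule,
    read_schedule_tsv,
    write_schedule_tsv,
)
from .unit_qc import DEFAULT_ATLAS, RegionGeometry

logger = logging.getLogger(__name__)

COHORTS = ("tactile", "visual")
LEARNING_STATES = ("naive", "shaped", "trained")


@dataclass
class UnitGroundTruth:
    """Generator parameters for one synthetic unit."""

    unit_id: str
    baseline_rate: float  # Hz
    region: str
    position: tuple[float, float, float]  # (AP, DV, ML) mm
    gain_tactile: float = 1.0
    gain_visual: float = 1.0
    response_latency: float = 0.05  # s
    response_duration: float = 1.0  # s
    offset_gain: float = 1.0
    coupling: dict = field(
        default_factory=lambda: {"pupil": 0.0, "whisk": 0.0, "lick": 0.0}
    )
    pupil_lag_s: float = 1.0
    dead_time_s: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if min(self.gain_tactile, self.gain_visual, self.offset_gain) < 0:
            raise ValueError("gains must be non-negative")
        if self.response_latency < 0:
            raise ValueError("latency must be non-negative")


@dataclass
class BehaviorParams:
    """Tunable behavior-generator parameters (rates in Hz, sizes in the
    trace's native units: pupil a.u., whisker degrees)."""

    lick_baseline_hz: float = 0.5
    lick_anticipatory_hz: float = 4.0
    lick_consumption_hz: float = 7.0
    lick_suppression_factor: float = 0.1
    consumption_window_s: float = 2.0
    pupil_rate_hz: float = 60.0
    pupil_baseline: float = 20.0
    pupil_drift_sd: float = 0.4
    pupil_drift_tau_s: float = 5.0
    pupil_constriction: float = 2.0
    pupil_dilation_puff: float = 2.0
    pupil_dilation_learned: float = 1.5
    pupil_learned_delay_s: float = 1.0
    whisker_rate_hz: float = 125.0
    whisk_setpoint_deg: float = 60.0
    whisk_base_halfamp_deg: float = 4.0
    whisk_puff_halfamp_deg: float = 8.0
    whisk_freq_hz: float = 8.0
    whisk_freq_jitter_hz: float = 1.0
    whisk_noise_deg: float = 0.3


@dataclass
class BehaviorTraces:
    """Simulated behavior for one session."""

    lick_times: np.ndarray
    pupil: FixedRateTrace
    whisker_angle: FixedRateTrace
    params: BehaviorParams
    cohort: str = "tactile"
    learning_state: str = "trained"
    # Runtime-only ground truth (not serialized): the amplitude envelope
    # actually used to modulate the whisker oscillation, in degrees
    # (protracted-minus-retracted convention, i.e. twice the half-amplitude).
    whisk_amplitude_truth: FixedRateTrace | None = None


@dataclass
class PopulationParams:
    """Defaults for a synthetic recorded population."""

    n_per_modality: int = 100
    pom_fraction: float = 0.75
    baseline_range_pom_hz: tuple[float, float] = (3.0, 20.0)
    baseline_range_lp_hz: tuple[float, float] = (2.0, 12.0)
    responsive_fraction: float = 0.6
    gain_range: tuple[float, float] = (2.0, 4.0)
    visual_base_gain_range: tuple[float, float] = (1.5, 3.0)
    ml_selectivity_slope: float = 2.0  # gain difference per mm ML, visual cohort
    offset_gain_fraction: float = 0.5
    offset_gain_range: tuple[float, float] = (1.5, 2.5)
    latency_range_s: tuple[float, float] = (0.02, 0.15)
    duration_range_s: tuple[float, float] = (0.8, 1.95)
    coupling_whisk_max: float = 0.15  # Hz per degree of whisking amplitude
    coupling_pupil_max: float = 0.4  # Hz per pupil unit
    coupling_lick_max: float = 0.3  # Hz per lick/s


@dataclass
class SyntheticSession:
    schedule: StimulusSchedule
    spikes: dict[str, np.ndarray]
    behavior: BehaviorTraces
    units: list[UnitGroundTruth]
    cohort: str
    seed: int
    population_params: PopulationParams


def _alpha_kernel(fs: float, rise_s: float, decay_s: float,
                  dur_s: float) -> np.ndarray:
    t = np.arange(0.0, dur_s, 1.0 / fs)
    k = (1.0 - np.exp(-t / rise_s)) * np.exp(-t / decay_s)
    peak = k.max()
    return k / peak if peak > 0 else k


def _event_signal(n: int, fs: float, event_times: np.ndarray,
                  kernel: np.ndarray) -> np.ndarray:
    imp = np.zeros(n)
    for t in np.atleast_1d(event_times):
        i = int(round(t * fs))
        if 0 <= i < n:
            imp[i] += 1.0
    return np.convolve(imp, kernel)[:n]


def poisson_times_from_rate(rate: np.ndarray, fs: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Discrete-time thinning: one Bernoulli draw per 1/fs bin.

    Valid while rate/fs stays well below 1 (at most one event per bin).
    """
    p = np.clip(rate / fs, 0.0, 1.0)
    idx = np.nonzero(rng.random(p.size) < p)[0]
    return idx / fs


def simulate_behavior(
    schedule: StimulusSchedule,
    cohort: str,
    learning_state: str,
    seed: int,
    params: BehaviorParams | None = None,
) -> BehaviorTraces:
    """Simulate licking, pupil, and whisking for one session.

    ``learning_state``: "naive" mice lick at baseline regardless of
    stimuli; "shaped" mice anticipate the CS+ and suppress licking during
    the CS- (the shaping task makes the unrewarded stimulus informative);
    "trained" mice anticipate the CS+ and ignore the CS-.
    """
    if cohort not in COHORTS:
        raise ValueError(f"unknown cohort {cohort!r}")
    if learning_state not in LEARNING_STATES:
        raise ValueError(f"unknown learning state {learning_state!r}")
    p = params or BehaviorParams()
    rng = np.random.default_rng(seed)
    T = schedule.session_length
    cs_plus = schedule.cs_plus
    cs_minus = "visual" if cs_plus == "tactile" else "tactile"

    # --- licking ---------------------------------------------------------
    fs_l = 200.0
    n_l = int(round(T * fs_l))
    lick_rate = np.full(n_l, p.lick_baseline_hz)
    if learning_state in ("shaped", "trained"):
        for e in schedule.events:
            i0 = int(round(e.onset_time * fs_l))
            i1 = int(round(e.offset_time * fs_l))
            if e.modality == cs_plus:
                lick_rate[i0:i1] = p.lick_anticipatory_hz
            elif learning_state == "shaped":
                lick_rate[i0:i1] = p.lick_baseline_hz * p.lick_suppression_factor
    for rt in schedule.reward_times:
        i0 = int(round(rt * fs_l))
        i1 = int(round((rt + p.consumption_window_s) * fs_l))
        lick_rate[i0:i1] = p.lick_consumption_hz
    lick_times = poisson_times_from_rate(lick_rate, fs_l, rng)

    # --- pupil (60 Hz) ---------------------------------------------------
    fs_p = p.pupil_rate_hz
    n_p = int(round(T * fs_p)) + 1
    drift = gaussian_filter1d(rng.standard_normal(n_p),
                              sigma=p.pupil_drift_tau_s * fs_p, mode="nearest")
    sd = drift.std()
    if sd > 0:
        drift *= p.pupil_drift_sd / sd
    pupil = np.full(n_p, p.pupil_baseline) + drift
    grating_on = schedule.onsets("visual")
    puff_on = schedule.onsets("tactile")
    pupil -= p.pupil_constriction * _event_signal(
        n_p, fs_p, grating_on, _alpha_kernel(fs_p, 0.3, 1.0, 4.0))
    pupil += p.pupil_dilation_puff * _event_signal(
        n_p, fs_p, puff_on, _alpha_kernel(fs_p, 0.5, 2.5, 8.0))
    if cohort == "visual" and learning_state in ("shaped", "trained"):
        pupil += p.pupil_dilation_learned * _event_signal(
            n_p, fs_p, grating_on + p.pupil_learned_delay_s,
            _alpha_kernel(fs_p, 0.5, 2.5, 8.0))

    # --- whisker angle (125 Hz) -----------------------------------------
    fs_w = p.whisker_rate_hz
    n_w = int(round(T * fs_w)) + 1
    freq = p.whisk_freq_hz + gaussian_filter1d(
        rng.standard_normal(n_w), sigma=1.0 * fs_w, mode="nearest")
    fsd = freq.std()
    if fsd > 0:
        freq = p.whisk_freq_hz + (freq - freq.mean()) * (p.whisk_freq_jitter_hz / fsd)
    phase = 2.0 * np.pi * np.cumsum(freq) / fs_w
    halfamp = p.whisk_base_halfamp_deg + p.whisk_puff_halfamp_deg * _event_signal(
        n_w, fs_w, puff_on, _alpha_kernel(fs_w, 0.15, 1.5, 6.0))
    angle = (p.whisk_setpoint_deg + halfamp * np.sin(phase)
             + p.whisk_noise_deg * rng.standard_normal(n_w))

    return BehaviorTraces(
        lick_times=lick_times,
        pupil=FixedRateTrace(pupil, fs_p),
        whisker_angle=FixedRateTrace(angle, fs_w),
        params=p,
        cohort=cohort,
        learning_state=learning_state,
        whisk_amplitude_truth=FixedRateTrace(2.0 * halfamp, fs_w),
    )


def _coupling_signals(behavior: BehaviorTraces, truth: UnitGroundTruth,
                      grid: np.ndarray, fs: float) -> dict[str, np.ndarray]:
    sig = {}
    pupil = behavior.pupil
    sig["pupil"] = np.interp(grid - truth.pupil_lag_s, pupil.times, pupil.values)
    amp = behavior.whisk_amplitude_truth
    if amp is None:
        from .physio_signals import whisk_amplitude
        amp = whisk_amplitude(behavior.whisker_angle).amplitude
    sig["whisk"] = np.interp(grid, amp.times, amp.values)
    counts = np.histogram(
        behavior.lick_times, bins=grid.size,
        range=(grid[0], grid[0] + grid.size / fs))[0].astype(float)
    sig["lick"] = uniform_filter1d(counts * fs, size=max(int(0.25 * fs), 1),
                                   mode="nearest")
    return sig


def spike_rate_vector(
    schedule: StimulusSchedule,
    truth: UnitGroundTruth,
    behavior: BehaviorTraces | None = None,
    fs: float = 1000.0,
) -> np.ndarray:
    """The exact rate function (Hz, on a 1/fs grid) used to draw spikes."""
    n = int(round(schedule.session_length * fs))
    gain = np.ones(n)
    for e in schedule.events:
        g = truth.gain_tactile if e.modality == "tactile" else truth.gain_visual
        i0 = int(round((e.onset_time + truth.response_latency) * fs))
        i1 = int(round((e.onset_time + truth.response_latency
                        + truth.response_duration) * fs))
        np.maximum(gain[i0:i1], g, out=gain[i0:i1])
        if e.rewarded and truth.offset_gain != 1.0:
            j0 = int(round(e.offset_time * fs))
            j1 = int(round((e.offset_time + 2.0) * fs))
            np.maximum(gain[j0:j1], truth.offset_gain, out=gain[j0:j1])
    rate = truth.baseline_rate * gain
    w = truth.coupling
    if behavior is not None and any(w.get(k, 0.0) != 0.0 for k in w):
        grid = np.arange(n) / fs
        signals = _coupling_signals(behavior, truth, grid, fs)
        for name, weight in w.items():
            if weight:
                s = signals[name]
                rate = rate + weight * (s - s.mean())
    n_neg = int(np.count_nonzero(rate < 0))
    if n_neg:
        logger.warning("unit %s: rate floored at 0 in %d of %d bins",
                       truth.unit_id, n_neg, n)
        rate = np.maximum(rate, 0.0)
    return rate


def simulate_spikes(
    schedule: StimulusSchedule,
    truth: UnitGroundTruth,
    behavior: BehaviorTraces | None,
    seed: int,
    fs: float = 1000.0,
) -> np.ndarray:
    """Draw one spike train by thinning the unit's rate function."""
    rate = spike_rate_vector(schedule, truth, behavior, fs)
    rng = np.random.default_rng(seed)
    times = poisson_times_from_rate(rate, fs, rng)
    if truth.dead_time_s > 0 and times.size:
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= truth.dead_time_s:
                kept.append(t)
        times = np.array(kept)
    return times


def _draw_unit(
    rng: np.random.Generator,
    unit_id: str,
    cohort: str,
    params: PopulationParams,
    atlas: RegionGeometry,
) -> UnitGroundTruth:
    region = "POm" if rng.random() < params.pom_fraction else "LP"
    box = atlas.regions[region]
    pos = tuple(float(rng.uniform(box.lo[i], box.hi[i])) for i in range(3))
    lo, hi = (params.baseline_range_pom_hz if region == "POm"
              else params.baseline_range_lp_hz)
    baseline = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    responsive = rng.random() < params.responsive_fraction
    gain_t, gain_v = 1.0, 1.0
    if responsive:
        if cohort == "tactile":
            gain_t = float(rng.uniform(*params.gain_range))
        else:
            base = float(rng.uniform(*params.visual_base_gain_range))
            ml = pos[2]
            box_mid = 0.5 * (box.lo[2] + box.hi[2])
            delta = params.ml_selectivity_slope * (ml - box_mid)
            gain_t = max(base + 0.5 * delta, 0.1)
            gain_v = max(base - 0.5 * delta, 0.1)
    offset_gain = (float(rng.uniform(*params.offset_gain_range))
                   if rng.random() < params.offset_gain_fraction else 1.0)
    return UnitGroundTruth(
        unit_id=unit_id,
        baseline_rate=baseline,
        region=region,
        position=pos,
        gain_tactile=gain_t,
        gain_visual=gain_v,
        response_latency=float(rng.uniform(*params.latency_range_s)),
        response_duration=float(rng.uniform(*params.duration_range_s)),
        offset_gain=offset_gain,
        coupling={
            "pupil": float(rng.uniform(0, params.coupling_pupil_max)),
            "whisk": float(rng.uniform(0, params.coupling_whisk_max)),
            "lick": float(rng.uniform(0, params.coupling_lick_max)),
        },
    )


def simulate_population(
    n_units: int,
    cohort: str,
    seed: int,
    params: PopulationParams | None = None,
    behavior_params: BehaviorParams | None = None,
    learning_state: str = "trained",
    atlas: RegionGeometry = DEFAULT_ATLAS,
) -> SyntheticSession:
    """Simulate a full recorded session: schedule, behavior, and units.

    In the visual cohort the tactile-minus-visual gain difference increases
    with the medial-lateral coordinate at ``params.ml_selectivity_slope``
    per mm, emulating a laterally clustered touch-selective subregion.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if cohort not in COHORTS:
        raise ValueError(f"unknown cohort {cohort!r}")
    params = params or PopulationParams()
    base = np.random.default_rng(seed)
    cs_plus = cohort  # reward follows the attended modality
    schedule = draw_full_schedule(
        params.n_per_modality, seed=int(base.integers(2**31)), cs_plus=cs_plus)
    behavior = simulate_behavior(
        schedule, cohort, learning_state, seed=int(base.integers(2**31)),
        params=behavior_params)
    units, spikes = [], {}
    for i in range(n_units):
        truth = _draw_unit(base, f"u{i:04d}", cohort, params, atlas)
        units.append(truth)
        spikes[truth.unit_id] = simulate_spikes(
            schedule, truth, behavior, seed=int(base.integers(2**31)))
    return SyntheticSession(
        schedule=schedule,
        spikes=spikes,
        behavior=behavior,
        units=units,
        cohort=cohort,
        seed=seed,
        population_params=params,
    )


# ---------------------------------------------------------------------------
# Session bundle I/O (directory of plain-text files)

def write_session(session: SyntheticSession, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_schedule_tsv(session.schedule, d / "schedule.tsv")
    with open(d / "spikes.tsv", "w", encoding="utf-8") as fh:
        fh.write("unit_id\ttime_s\n")
        for uid in sorted(session.spikes):
            for t in session.spikes[uid]:
                fh.write(f"{uid}\t{t:.3f}\n")
    with open(d / "units.tsv", "w", encoding="utf-8") as fh:
        fh.write("unit_id\tAP_mm\tDV_mm\tML_mm\tregion\n")
        for u in session.units:
            ap, dv, ml = u.position
            fh.write(f"{u.unit_id}\t{ap!r}\t{dv!r}\t{ml!r}\t{u.region}\n")
    with open(d / "licks.tsv", "w", encoding="utf-8") as fh:
        fh.write("time_s\n")
        for t in session.behavior.lick_times:
            fh.write(f"{t:.4f}\n")
    write_trace_csv(session.behavior.pupil, d / "pupil.csv")
    write_trace_csv(session.behavior.whisker_angle, d / "whisker.csv")
    truth = {
        "seed": session.seed,
        "cohort": session.cohort,
        "learning_state": session.behavior.learning_state,
        "behavior_params": asdict(session.behavior.params),
        "units": [asdict(u) for u in session.units],
    }
    with open(d / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1)
    with open(d / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {"seed": session.seed, "cohort": session.cohort,
             "population_params": asdict(session.population_params)},
            fh, sort_keys=True)


def read_session(directory) -> SyntheticSession:
    d = Path(directory)
    for name in ("schedule.tsv", "spikes.tsv", "units.tsv", "licks.tsv",
                 "pupil.csv", "whisker.csv", "truth.json", "config.yaml"):
        if not (d / name).exists():
            raise FileNotFoundError(f"session bundle is missing {name}")
    schedule = read_schedule_tsv(d / "schedule.tsv")
    spikes: dict[str, list[float]] = {}
    with open(d / "spikes.tsv", encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            uid, t = line.split("\t")
            spikes.setdefault(uid, []).append(float(t))
    with open(d / "truth.json", encoding="utf-8") as fh:
        truth = json.load(fh)
    units = []
    for u in truth["units"]:
        u = dict(u)
        u["position"] = tuple(u["position"])
        units.append(UnitGroundTruth(**u))
    for u in units:  # units with zero spikes still appear in the bundle
        spikes.setdefault(u.unit_id, [])
    with open(d / "licks.tsv", encoding="utf-8") as fh:
        fh.readline()
        licks = np.array([float(line) for line in fh if line.strip()])
    with open(d / "config.yaml", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    pp = cfg.get("population_params", {})
    for key in ("baseline_range_pom_hz", "baseline_range_lp_hz", "gain_range",
                "visual_base_gain_range", "offset_gain_range",
                "latency_range_s", "duration_range_s"):
        if key in pp:
            pp[key] = tuple(pp[key])
    behavior = BehaviorTraces(
        lick_times=licks,
        pupil=read_trace_csv(d / "pupil.csv"),
        whisker_angle=read_trace_csv(d / "whisker.csv"),
        params=BehaviorParams(**truth["behavior_params"]),
        cohort=truth["cohort"],
        learning_state=truth["learning_state"],
        whisk_amplitude_truth=None,
    )
    return SyntheticSession(
        schedule=schedule,
        spikes={uid: np.array(ts) for uid, ts in spikes.items()},
        behavior=behavior,
        units=units,
        cohort=truth["cohort"],
        seed=int(truth["seed"]),
        population_params=PopulationParams(**pp),
    )
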