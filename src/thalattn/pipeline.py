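"""End-to-end orchestration: simulate a session bundle, analyze it, and
run the recovery suite, with YAML configuration and reproducible outputs.

Every analysis parameter left open by the methods (window lengths, blink
threshold, bin widths, alpha, ISI rounding mode, ...) appears in
``RunConfig`` with its default, and every output table carries the config
hash in a comment header so results can be traced to their settings.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior_metrics import lick_index, session_learning_tests
from .movement_model import (
    bin_session,
    event_aligned_series,
    firing_behavior_xcorr,
    fit_movement_model,
    residual_psth,
)
from .physio_signals import TraceRejectedError, clean_pupil_trace, whisk_amplitude
from .recovery import run_recovery_suite
from .response_stats import (
    build_trial_windows,
    classify_responses,
    offset_period_analysis,
    response_latency,
    retained_presentations,
)
from .synthetic_session import (
    PopulationParams,
    SyntheticSession,
    read_session,
    simulate_population,
    write_session,
)
from .unit_qc import (
    DEFAULT_ATLAS,
    UnitRecord,
    refractory_violation_fraction,
    session_quiet_epochs,
    spontaneous_rate,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of a pipeline run (YAML-serializable)."""

    seed: int = 0
    cohort: str = "tactile"
    task_phase: str = "full"
    learning_state: str = "trained"
    n_units: int = 20
    n_per_modality: int = 60
    ml_selectivity_slope: float = 2.0
    alpha: float = 0.05
    # lick index
    li_baseline_window_s: float = 2.0
    li_onset_exclusion_s: float = 0.05
    min_shaping_sessions: int = 3
    min_full_sessions: int = 4
    # pupil cleaning
    pupil_smooth_frames: int = 5
    pupil_median_window_s: float = 3.0
    pupil_deviation_fraction: float = 0.25
    # whisking
    whisk_band_hz: tuple[float, float] = (4.0, 30.0)
    # unit QC
    refractory_threshold_s: float = 0.003
    max_violation_fraction: float = 0.10
    border_exclusion_mm: float = 0.050
    quiet_pre_s: float = 2.0
    quiet_min_length_s: float = 6.0
    # response stats
    cross_modal_exclusion_s: float = 6.0
    latency_bin_s: float = 0.010
    latency_search_s: float = 0.5
    latency_z: float = 2.576
    # movement model
    bin_width_s: float = 0.25
    xcorr_bin_s: float = 0.10
    xcorr_max_lag_s: float = 3.0
    # documented open-choice settings
    isi_binning: str = "round_nearest_second"
    isi_cap_mode: str = "clip_at_55_s"
    li_undefined_policy: str = "exclude_from_session_mean"
    regression_scope: str = "whole_session_bins"

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.cohort not in ("tactile", "visual"):
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")

    @property
    def config_hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "whisk_band_hz" in data:
            data["whisk_band_hz"] = tuple(data["whisk_band_hz"])
        return cls(**data)


def _write_table(df: pd.DataFrame, path, config_hash: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t" if str(path).endswith(".tsv") else ",",
                  index=False)


def run_simulation(config: RunConfig, out_dir) -> SyntheticSession:
    """Simulate a session per the config and write the bundle to disk."""
    params = PopulationParams(
        n_per_modality=config.n_per_modality,
        ml_selectivity_slope=config.ml_selectivity_slope,
    )
    session = simulate_population(
        config.n_units, config.cohort, config.seed, params=params,
        learning_state=config.learning_state)
    out = Path(out_dir)
    write_session(session, out)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump({"seed": config.seed, "thalattn_version": __version__,
                   "config_hash": config.config_hash}, fh, indent=1)
    return session


def _percent(n: int, total: int) -> str:
    return f"{n} ({100.0 * n / total:.1f}%)" if total else "0 (0.0%)"


def run_analysis(config: RunConfig, bundle_dir, out_dir) -> dict:
    """Run every analysis stage on a session bundle; return the summary."""
    session = read_session(bundle_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash
    schedule = session.schedule
    cs_plus = schedule.cs_plus
    cs_minus = "visual" if cs_plus == "tactile" else "tactile"
    dropped_log: list[str] = []

    # --- behavior --------------------------------------------------------
    li_records = {m: [] for m in ("tactile", "visual")}
    li_rows = []
    for i, e in enumerate(schedule.events):
        rec = lick_index(session.behavior.lick_times, e,
                         baseline_window_s=config.li_baseline_window_s,
                         onset_exclusion_s=config.li_onset_exclusion_s)
        li_records[e.modality].append(rec)
        li_rows.append({
            "stim_id": i, "modality": e.modality,
            "licks_baseline": rec.licks_baseline,
            "licks_stimulus": rec.licks_stimulus,
            "LI": np.nan if rec.li is None else rec.li,
        })
        if rec.li is None:
            dropped_log.append(f"presentation {i}: undefined LI (no licks)")
    _write_table(pd.DataFrame(li_rows), out / "lick_index.tsv", chash)
    learning = session_learning_tests(
        li_records[cs_plus], li_records[cs_minus],
        n_sessions_shaping=config.min_shaping_sessions,
        n_sessions_full=config.min_full_sessions,
        alpha=config.alpha)
    def _sem(records):
        vals = np.array([r.li for r in records if r.defined])
        return (float(vals.std(ddof=1) / np.sqrt(vals.size))
                if vals.size > 1 else None)

    behavior_summary = {
        "cs_plus": cs_plus,
        "mean_li_cs_plus": learning.mean_li_cs_plus,
        "sem_li_cs_plus": _sem(li_records[cs_plus]),
        "mean_li_cs_minus": learning.mean_li_cs_minus,
        "sem_li_cs_minus": _sem(li_records[cs_minus]),
        "p_cs_plus": learning.p_cs_plus,
        "p_cs_minus": learning.p_cs_minus,
        "advance_to_full": learning.advance_to_full,
        "training_complete": learning.training_complete,
    }

    # --- unit QC ---------------------------------------------------------
    epochs = session_quiet_epochs(
        schedule, session.behavior.lick_times,
        pre_quiet_s=config.quiet_pre_s, min_length_s=config.quiet_min_length_s)
    qc_records: dict[str, UnitRecord] = {}
    positions = {u.unit_id: u.position for u in session.units}
    for uid, spk in session.spikes.items():
        frac = refractory_violation_fraction(spk) if len(spk) >= 2 else float("nan")
        ok = (not np.isnan(frac)) and frac <= config.max_violation_fraction
        region, border = DEFAULT_ATLAS.assign(
            positions[uid], border_mm=config.border_exclusion_mm)
        if not ok:
            dropped_log.append(f"unit {uid}: refractory violations "
                               f"{frac:.3f} > {config.max_violation_fraction}")
        if region == "border":
            dropped_log.append(f"unit {uid}: within "
                               f"{config.border_exclusion_mm * 1000:.0f} um "
                               "of a region border")
        qc_records[uid] = UnitRecord(
            unit_id=uid, n_spikes=len(spk), violation_fraction=frac,
            qc_pass=ok, region=region, border_distance_mm=border,
            spontaneous_rate_hz=spontaneous_rate(spk, epochs),
            position=positions[uid])
    qc_df = pd.DataFrame([{
        "unit_id": r.unit_id, "n_spikes": r.n_spikes,
        "violation_fraction": r.violation_fraction, "qc_pass": r.qc_pass,
        "region": r.region, "border_distance_mm": r.border_distance_mm,
        "spontaneous_rate_hz": (np.nan if r.spontaneous_rate_hz is None
                                else r.spontaneous_rate_hz),
    } for r in qc_records.values()])
    _write_table(qc_df, out / "units_qc.tsv", chash)

    # --- response statistics (per cohort x region family) ----------------
    included = [uid for uid, r in qc_records.items()
                if r.qc_pass and r.region in ("POm", "LP")]
    windows = {uid: build_trial_windows(session.spikes[uid], schedule)
               for uid in included}
    n_all = len(schedule.events)
    n_kept = len(retained_presentations(schedule))
    dropped_log.append(f"{n_all - n_kept} of {n_all} presentations dropped "
                       "by the 6-s cross-modal overlap exclusion")
    resp_frames = []
    for region in ("POm", "LP"):
        fam = {uid: windows[uid] for uid in included
               if qc_records[uid].region == region}
        if not fam:
            continue
        res = classify_responses(fam, alpha=config.alpha)
        res.insert(0, "region", region)
        resp_frames.append(res)
    responses = (pd.concat(resp_frames) if resp_frames
                 else pd.DataFrame())
    if not responses.empty:
        for mod, col in (("tactile", "latency_puff_s"),
                         ("visual", "latency_grating_s")):
            onsets = np.array([e.onset_time for e in
                               retained_presentations(schedule)
                               if e.modality == mod])
            lat = {}
            for uid in responses.index:
                if responses.loc[uid, "significant"] and onsets.size >= 10:
                    lat[uid] = response_latency(
                        session.spikes[uid], onsets,
                        bin_width=config.latency_bin_s,
                        search_dur=config.latency_search_s,
                        z=config.latency_z)
                else:
                    lat[uid] = None
            responses[col] = [np.nan if lat[u] is None else lat[u]
                              for u in responses.index]
        for mod, col in (("tactile", "offset_rate_puff_hz"),
                         ("visual", "offset_rate_grating_hz")):
            responses[col] = [
                windows[uid][windows[uid].modality == mod].offset_rate.mean()
                for uid in responses.index]
    _write_table(responses.reset_index(), out / "responses.tsv", chash)
    offset_report = offset_period_analysis({session.cohort: windows})
    with open(out / "offset_analysis.json", "w", encoding="utf-8") as fh:
        json.dump({"config_hash": chash,
                   "within_cohort": offset_report["within_cohort"]},
                  fh, indent=1, default=float)

    # --- movement regression --------------------------------------------
    try:
        pupil = clean_pupil_trace(
            session.behavior.pupil,
            smooth_frames=config.pupil_smooth_frames,
            median_window_s=config.pupil_median_window_s,
            deviation_fraction=config.pupil_deviation_fraction)
    except TraceRejectedError as err:
        logger.warning("pupil trace rejected: %s", err)
        pupil = session.behavior.pupil
    amp = whisk_amplitude(session.behavior.whisker_angle,
                          band_hz=config.whisk_band_hz).amplitude
    traces = {"whisk": amp, "pupil": pupil}
    binned = bin_session(schedule.session_length,
                         {uid: session.spikes[uid] for uid in included},
                         session.behavior.lick_times, traces,
                         bin_width=config.bin_width_s)
    fit_rows, psth_rows = [], []
    for uid in included:
        fit = fit_movement_model(binned, uid)
        fit_rows.append({
            "unit_id": uid, "b0": fit.intercept,
            "b_whisk": fit.coefficients.get("whisk", np.nan),
            "b_pupil": fit.coefficients.get("pupil", np.nan),
            "b_lick": fit.coefficients.get("lick", np.nan),
            "R2": fit.r2,
        })
        for mod in ("tactile", "visual"):
            onsets = np.array([e.onset_time for e in
                               retained_presentations(schedule)
                               if e.modality == mod])
            psth = residual_psth(fit, binned, onsets)
            for t, v in zip(psth.time_rel, psth.mean):
                psth_rows.append({"unit_id": uid, "modality": mod,
                                  "time_s": t, "value": v})
    _write_table(pd.DataFrame(fit_rows), out / "movement_fits.tsv", chash)
    _write_table(pd.DataFrame(psth_rows), out / "residual_psth.csv", chash)

    xbinned = bin_session(schedule.session_length,
                          {uid: session.spikes[uid] for uid in included},
                          session.behavior.lick_times, traces,
                          bin_width=config.xcorr_bin_s)
    xc_rows = []
    for uid in included:
        for pred in ("pupil", "whisk", "lick"):
            lags, corr = firing_behavior_xcorr(
                xbinned.rates[uid], xbinned.predictors[pred],
                config.xcorr_bin_s, max_lag_s=config.xcorr_max_lag_s)
            for lag, c in zip(lags, corr):
                xc_rows.append({"unit_id": uid, "predictor": pred,
                                "lag_s": lag, "value": c})
    _write_table(pd.DataFrame(xc_rows), out / "xcorr.csv", chash)

    # --- summary ---------------------------------------------------------
    n_inc = len(included)
    label_counts = (responses.label.value_counts().to_dict()
                    if not responses.empty else {})
    n_sig = int(responses.significant.sum()) if not responses.empty else 0
    summary = {
        "config_hash": chash,
        "seed": session.seed,
        "cohort": session.cohort,
        "n_units_total": len(session.spikes),
        "n_units_included": n_inc,
        "n_presentations_total": n_all,
        "n_presentations_retained": n_kept,
        "significantly_responding": _percent(n_sig, n_inc),
        "labels": {lab: _percent(int(n), n_inc)
                   for lab, n in sorted(label_counts.items())},
        "behavior": behavior_summary,
        "dropped": dropped_log,
    }
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, default=float)
    return summary


def run_recovery(config: RunConfig, out_dir, fast: bool = False) -> dict:
    """Run the recovery suite and write its JSON report."""
    report = run_recovery_suite(config.seed, fast=fast)
    report["config_hash"] = config.config_hash
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "recovery_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report
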