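"""Per-unit sensory-response statistics.

For each unit and each retained stimulus presentation, spikes are counted
in a baseline window (1 s before onset), a stimulus window (first 1 s of
the stimulus), and an offset window (2 s after stimulus offset); the
+/-50 ms around onset is ambiguous and excluded. Presentations where the
two modalities fall within 6 s of each other are excluded entirely.

A unit responds significantly if a one-way ANOVA across {all baseline
rates, air-puff-period rates, grating-period rates} survives a
Holm-Bonferroni correction applied over all units of one cohort x region
family. Significant units are then labelled "puff", "grating", "both", or
"none" by paired Wilcoxon signed-rank tests of stimulus-period versus
same-presentation baseline rates (uncorrected, alpha = 0.05).

The selectivity index of a responsive unit is

    SI = (|FR_A - FR_B| - |FR_V - FR_B|) / (|FR_A - FR_B| + |FR_V - FR_B|)

with FR_B the mean baseline rate, FR_A the mean air-puff-period rate and
FR_V the mean grating-period rate: +1 means the unit responds only to the
air puff, -1 only to the grating, 0 equally to both.

Response latency is detected on the trial-averaged rate in 10-ms bins: the
first run of at least two consecutive bins whose rate leaves a 99%
confidence band (2.576 baseline SDs) of the baseline rate, starting within
500 ms of onset.

A linear model relates SI to anatomical position and conditioning type:
SI ~ 1 + DV + ML + AP + CT + CT:DV + CT:ML + CT:AP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .task_design import StimulusSchedule

logger = logging.getLogger(__name__)

CROSS_MODAL_EXCLUSION_S = 6.0
AMBIGUITY_S = 0.05
BASELINE_WINDOW_S = 1.0
STIMULUS_WINDOW_S = 1.0
OFFSET_WINDOW_S = 2.0


@dataclass
class PositionModelFit:
    params: pd.Series
    pvalues: pd.Series
    model_p: float
    adjusted_r2: float
    n: int


def retained_presentations(schedule: StimulusSchedule) -> list:
    """Presentations surviving the 6-s cross-modal overlap exclusion.

    A presentation is dropped when any stimulus of the *other* modality has
    an onset within 6 s of its own onset; the exclusion is symmetric, so
    both members of a colliding pair are dropped.
    """
    events = schedule.events
    onsets = {m: schedule.onsets(m) for m in ("tactile", "visual")}
    kept = []
    for e in events:
        other = onsets["visual" if e.modality == "tactile" else "tactile"]
        if other.size and np.min(np.abs(other - e.onset_time)) <= CROSS_MODAL_EXCLUSION_S:
            continue
        kept.append(e)
    return kept


def build_trial_windows(
    spike_times: np.ndarray,
    schedule: StimulusSchedule,
) -> pd.DataFrame:
    """Per-presentation spike counts and rates in the three analysis windows.

    One row per retained presentation with columns: modality, onset,
    baseline/stimulus/offset counts and rates. The baseline and stimulus
    windows span 0.95 s each (1-s windows minus the 50-ms ambiguity band);
    the offset window spans the 2 s after stimulus offset.
    """
    t = np.asarray(spike_times, dtype=float)
    rows = []
    b_dur = BASELINE_WINDOW_S - AMBIGUITY_S
    s_dur = STIMULUS_WINDOW_S - AMBIGUITY_S
    for i, e in enumerate(retained_presentations(schedule)):
        on, off = e.onset_time, e.offset_time
        n_b = int(np.count_nonzero((t >= on - BASELINE_WINDOW_S)
                                   & (t < on - AMBIGUITY_S)))
        n_s = int(np.count_nonzero((t > on + AMBIGUITY_S)
                                   & (t <= on + STIMULUS_WINDOW_S)))
        n_o = int(np.count_nonzero((t > off) & (t <= off + OFFSET_WINDOW_S)))
        rows.append({
            "stimulus_id": i,
            "modality": e.modality,
            "onset_s": on,
            "baseline_count": n_b,
            "stimulus_count": n_s,
            "offset_count": n_o,
            "baseline_rate": n_b / b_dur,
            "stimulus_rate": n_s / s_dur,
            "offset_rate": n_o / OFFSET_WINDOW_S,
        })
    df = pd.DataFrame(rows, columns=[
        "stimulus_id", "modality", "onset_s", "baseline_count",
        "stimulus_count", "offset_count", "baseline_rate", "stimulus_rate",
        "offset_rate"])
    if df.empty:
        logger.warning("no presentations retained after overlap exclusion")
    return df


def selectivity_index(fr_b: float, fr_a: float, fr_v: float) -> float | None:
    """Selectivity index; None (undefined) when neither stimulus-period
    rate deviates from baseline."""
    for v in (fr_b, fr_a, fr_v):
        if not np.isfinite(v):
            raise ValueError("firing rates must be finite")
    da = abs(fr_a - fr_b)
    dv = abs(fr_v - fr_b)
    if da + dv == 0:
        return None
    return (da - dv) / (da + dv)


def _paired_signed_rank(stim: np.ndarray, base: np.ndarray) -> float:
    diff = stim - base
    if np.all(diff == 0):
        return 1.0
    return float(stats.wilcoxon(stim, base).pvalue)


def classify_responses(
    windows_by_unit: dict[str, pd.DataFrame],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify every unit of one correction family (cohort x region).

    Returns one row per unit: mean rates (fr_b, fr_a, fr_v), the ANOVA p
    value, its Holm-Bonferroni-corrected p value, the significance flag,
    the response label, and the selectivity index (NaN for units without a
    significant response or with an undefined SI).
    """
    recs = []
    for uid, df in windows_by_unit.items():
        puff = df[df.modality == "tactile"]
        grat = df[df.modality == "visual"]
        rec = {
            "unit_id": uid,
            "n_trials_puff": len(puff),
            "n_trials_grating": len(grat),
            "fr_b": df.baseline_rate.mean() if len(df) else np.nan,
            "fr_a": puff.stimulus_rate.mean() if len(puff) else np.nan,
            "fr_v": grat.stimulus_rate.mean() if len(grat) else np.nan,
            "anova_p": np.nan,
            "testable": False,
        }
        if len(puff) >= 2 and len(grat) >= 2:
            groups = [df.baseline_rate.values, puff.stimulus_rate.values,
                      grat.stimulus_rate.values]
            pooled = np.concatenate(groups)
            if np.ptp(pooled) > 0:
                rec["anova_p"] = float(stats.f_oneway(*groups).pvalue)
                rec["testable"] = True
        recs.append(rec)
    out = pd.DataFrame(recs).set_index("unit_id")
    out["corrected_p"] = np.nan
    out["significant"] = False
    testable = out.index[out.testable]
    if len(testable):
        reject, p_corr, _, _ = multipletests(
            out.loc[testable, "anova_p"].values, alpha=alpha, method="holm")
        out.loc[testable, "corrected_p"] = p_corr
        out.loc[testable, "significant"] = reject
    out["p_puff"] = np.nan
    out["p_grating"] = np.nan
    out["label"] = "none"
    out["si"] = np.nan
    for uid in out.index[out.significant]:
        df = windows_by_unit[uid]
        puff = df[df.modality == "tactile"]
        grat = df[df.modality == "visual"]
        p_p = _paired_signed_rank(puff.stimulus_rate.values,
                                  puff.baseline_rate.values)
        p_g = _paired_signed_rank(grat.stimulus_rate.values,
                                  grat.baseline_rate.values)
        out.loc[uid, "p_puff"] = p_p
        out.loc[uid, "p_grating"] = p_g
        resp_p, resp_g = p_p < alpha, p_g < alpha
        out.loc[uid, "label"] = ("both" if resp_p and resp_g
                                 else "puff" if resp_p
                                 else "grating" if resp_g
                                 else "none")
        si = selectivity_index(out.loc[uid, "fr_b"], out.loc[uid, "fr_a"],
                               out.loc[uid, "fr_v"])
        out.loc[uid, "si"] = np.nan if si is None else si
    return out


def response_latency(
    spike_times: np.ndarray,
    onsets: np.ndarray,
    bin_width: float = 0.010,
    baseline_dur: float = 1.0,
    search_dur: float = 0.5,
    z: float = 2.576,
    min_run: int = 2,
    sd_floor: float = 1e-6,
) -> float | None:
    """Response latency from the trial-averaged PSTH, or None.

    Latency is the left edge of the first bin after onset that begins a run
    of at least ``min_run`` consecutive bins whose rate deviates from the
    baseline mean by more than ``z`` baseline SDs (two-sided: increases and
    decreases both count). Units whose rate never crosses the band within
    ``search_dur`` of onset return None.
    """
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size < 10:
        raise ValueError("at least 10 retained presentations are required")
    t = np.asarray(spike_times, dtype=float)
    lo, hi = -baseline_dur, search_dur + min_run * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts = np.zeros(edges.size - 1)
    for on in onsets:
        counts += np.histogram(t - on, bins=edges)[0]
    rate = counts / (onsets.size * bin_width)
    centers = edges[:-1]
    base = rate[centers < -bin_width / 2]
    mu, sd = base.mean(), base.std(ddof=0)
    if sd == 0:
        logger.info("zero baseline SD; floored at %g", sd_floor)
        sd = sd_floor
    dev = np.abs(rate - mu) > z * sd
    start_idx = np.nonzero(centers >= -bin_width / 2)[0][0]
    last_start = np.nonzero(centers < search_dur - bin_width / 2)[0][-1]
    for i in range(start_idx, last_start + 1):
        if np.all(dev[i:i + min_run]) and i + min_run <= dev.size:
            return float(centers[i])
    return None


def offset_period_analysis(
    windows_by_cohort: dict[str, dict[str, pd.DataFrame]],
) -> dict:
    """Group comparisons of baseline-subtracted stimulus and offset rates.

    Per unit and modality, delta = mean(period rate) - mean(baseline rate)
    for the stimulus and offset periods. Within each cohort: paired
    signed-rank of offset delta versus zero per modality and air-puff
    versus grating. Across cohorts (when both are supplied): two-way ANOVA
    (conditioning type x stimulus type) on the deltas per period.
    """
    rows = []
    for cohort, by_unit in windows_by_cohort.items():
        for uid, df in by_unit.items():
            for mod in ("tactile", "visual"):
                sub = df[df.modality == mod]
                if sub.empty:
                    continue
                rows.append({
                    "cohort": cohort,
                    "unit_id": uid,
                    "modality": mod,
                    "d_stimulus": sub.stimulus_rate.mean() - sub.baseline_rate.mean(),
                    "d_offset": sub.offset_rate.mean() - sub.baseline_rate.mean(),
                })
    deltas = pd.DataFrame(rows)
    report: dict = {"deltas": deltas, "within_cohort": {}, "anova": {}}
    for cohort, grp in deltas.groupby("cohort"):
        wide = grp.pivot(index="unit_id", columns="modality", values="d_offset")
        entry: dict = {}
        for mod in ("tactile", "visual"):
            if mod in wide:
                vals = wide[mod].dropna().values
                entry[f"offset_vs_zero_{mod}_p"] = (
                    _paired_signed_rank(vals, np.zeros_like(vals))
                    if vals.size else np.nan)
        if {"tactile", "visual"} <= set(wide.columns):
            both = wide.dropna()
            entry["offset_puff_vs_grating_p"] = _paired_signed_rank(
                both["tactile"].values, both["visual"].values)
            sw = grp.pivot(index="unit_id", columns="modality",
                           values="d_stimulus").dropna()
            entry["stimulus_puff_vs_grating_p"] = _paired_signed_rank(
                sw["tactile"].values, sw["visual"].values)
        report["within_cohort"][cohort] = entry
    if deltas.cohort.nunique() >= 2:
        for period in ("d_stimulus", "d_offset"):
            model = smf.ols(f"{period} ~ C(cohort) * C(modality)",
                            data=deltas).fit()
            table = sm.stats.anova_lm(model, typ=2)
            report["anova"][period] = {
                "cohort_p": float(table.loc["C(cohort)", "PR(>F)"]),
                "modality_p": float(table.loc["C(modality)", "PR(>F)"]),
                "interaction_p": float(
                    table.loc["C(cohort):C(modality)", "PR(>F)"]),
            }
    return report


def position_selectivity_model(records: pd.DataFrame) -> PositionModelFit:
    """Fit SI ~ 1 + DV + ML + AP + CT + CT:DV + CT:ML + CT:AP.

    ``records`` needs columns si, AP, DV, ML, cohort (two levels). Requires
    at least 20 units with a defined SI and both cohorts present; raises on
    a rank-deficient design (e.g. identical positions).
    """
    df = records.dropna(subset=["si"]).copy()
    if len(df) < 20:
        raise ValueError("at least 20 units with a defined SI are required")
    if df.cohort.nunique() < 2:
        raise ValueError("both cohorts must be present")
    model = smf.ols(
        "si ~ DV + ML + AP + C(cohort) + C(cohort):DV + C(cohort):ML"
        " + C(cohort):AP", data=df)
    X = model.exog
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient "
                         "(degenerate positions or cohort coding)")
    fit = model.fit()
    return PositionModelFit(
        params=fit.params,
        pvalues=fit.pvalues,
        model_p=float(fit.f_pvalue),
        adjusted_r2=float(fit.rsquared_adj),
        n=len(df),
    )
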