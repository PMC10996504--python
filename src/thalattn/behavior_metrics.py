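"""Lick detection, lick index, and session learning-criterion tests.

The lick index (LI) for one stimulus presentation compares licking during
the 2-s stimulus with licking in the 2 s before stimulus onset:

    LI = (licks_stimulus - licks_baseline) / (licks_stimulus + licks_baseline)

LI is +1 when the mouse licks only during the stimulus (anticipation), -1
when it licks only before (withholding), 0 when it ignores the stimulus,
and undefined when it licks in neither window. Licks within ±50 ms of
stimulus onset are excluded as ambiguous.

Session criteria: a mouse advances from the shaping to the full task once
the session's CS+ LIs are significantly greater than zero (one-sided
Wilcoxon signed-rank, minimum three shaping sessions), and training is
complete once the CS- LIs are no longer significantly different from zero
(two-sided, minimum four full-task sessions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .physio_signals import FixedRateTrace
from .task_design import StimulusEvent


@dataclass
class LickIndexRecord:
    stimulus_onset: float
    modality: str
    licks_baseline: int
    licks_stimulus: int
    li: float | None
    rate_normalized: bool = False

    @property
    def defined(self) -> bool:
        return self.li is not None


@dataclass
class LearningReport:
    p_cs_plus: float | None
    p_cs_minus: float | None
    mean_li_cs_plus: float | None
    mean_li_cs_minus: float | None
    n_defined_cs_plus: int
    n_defined_cs_minus: int
    advance_to_full: bool | None
    training_complete: bool | None


def detect_licks(
    analog: FixedRateTrace,
    threshold: float,
    debounce_s: float = 0.05,
) -> np.ndarray:
    """Lick times from upward threshold crossings of the lick-port signal.

    Crossings closer together than ``debounce_s`` are merged (the first of
    each cluster is kept). A flat signal yields no licks.
    """
    v = analog.values
    up = np.nonzero((v[:-1] < threshold) & (v[1:] >= threshold))[0] + 1
    times = analog.start_time + up / analog.sample_rate
    if times.size == 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= debounce_s:
            kept.append(t)
    return np.array(kept)


def lick_index(
    lick_times: np.ndarray,
    stimulus: StimulusEvent,
    baseline_window_s: float = 2.0,
    onset_exclusion_s: float = 0.05,
) -> LickIndexRecord:
    """Lick index for one presentation.

    Baseline counts licks in [onset-2 s, onset-0.05 s); stimulus counts
    licks in (onset+0.05 s, offset]. If the stimulus duration differs from
    the baseline window, both counts are converted to rates before the
    formula so the comparison stays fair (flagged ``rate_normalized``).
    """
    t = np.asarray(lick_times, dtype=float)
    on = stimulus.onset_time
    b_lo, b_hi = on - baseline_window_s, on - onset_exclusion_s
    s_lo, s_hi = on + onset_exclusion_s, on + stimulus.duration
    n_b = int(np.count_nonzero((t >= b_lo) & (t < b_hi)))
    n_s = int(np.count_nonzero((t > s_lo) & (t <= s_hi)))
    normalize = not np.isclose(stimulus.duration, baseline_window_s)
    a, b = float(n_s), float(n_b)
    if normalize:
        a /= stimulus.duration
        b /= baseline_window_s
    li = None if a + b == 0 else (a - b) / (a + b)
    return LickIndexRecord(
        stimulus_onset=on,
        modality=stimulus.modality,
        licks_baseline=n_b,
        licks_stimulus=n_s,
        li=li,
        rate_normalized=normalize,
    )


def _signed_rank_vs_zero(values: np.ndarray, alternative: str) -> float | None:
    nonzero = values[values != 0]
    if values.size == 0:
        return None
    if nonzero.size == 0:
        return 1.0  # every LI exactly zero: no evidence against zero median
    res = stats.wilcoxon(values, alternative=alternative)
    return float(res.pvalue)


def session_learning_tests(
    records_cs_plus: list[LickIndexRecord],
    records_cs_minus: list[LickIndexRecord],
    n_sessions_shaping: int = 0,
    n_sessions_full: int = 0,
    alpha: float = 0.05,
    min_shaping_sessions: int = 3,
    min_full_sessions: int = 4,
) -> LearningReport:
    """Evaluate the advance-to-full and training-complete criteria.

    Presentations with an undefined LI (no licks in either window) are
    excluded from the session mean and from the tests. When all LIs of a
    type are undefined the corresponding criterion is reported as not
    evaluable (``None``).
    """
    li_plus = np.array([r.li for r in records_cs_plus if r.defined])
    li_minus = np.array([r.li for r in records_cs_minus if r.defined])
    p_plus = _signed_rank_vs_zero(li_plus, "greater") if li_plus.size else None
    p_minus = _signed_rank_vs_zero(li_minus, "two-sided") if li_minus.size else None
    advance = None
    if p_plus is not None:
        advance = bool(p_plus < alpha and n_sessions_shaping >= min_shaping_sessions)
    complete = None
    if p_minus is not None:
        complete = bool(p_minus >= alpha and n_sessions_full >= min_full_sessions)
    return LearningReport(
        p_cs_plus=p_plus,
        p_cs_minus=p_minus,
        mean_li_cs_plus=float(li_plus.mean()) if li_plus.size else None,
        mean_li_cs_minus=float(li_minus.mean()) if li_minus.size else None,
        n_defined_cs_plus=int(li_plus.size),
        n_defined_cs_minus=int(li_minus.size),
        advance_to_full=advance,
        training_complete=complete,
    )
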