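"""Stimulus schedules for the cross-modal conditioning task.

Two task phases are used when conditioning head-fixed mice:

* **shaping** — a classic trial structure: tactile (air puff) and visual
  (drifting grating) stimuli alternate in random balanced order with a
  uniform 8–12 s gap between consecutive events, so the unrewarded stimulus
  is informative about reward timing.
* **full** — the two modality streams are drawn independently; within a
  stream the interval to the next stimulus is Exponential(mean 10 s) plus a
  Uniform(8, 12) s offset, clipped at 55 s and rounded to whole seconds.
  Past the offset support the memoryless exponential makes the hazard rate
  of the next stimulus flat, so neither stimulus predicts the other or the
  reward.

Every stimulus lasts 2 s; the rewarded (CS+) modality triggers a water
reward at stimulus offset.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MODALITIES = ("tactile", "visual")
TASK_PHASES = ("shaping", "full")
STIMULUS_DURATION_S = 2.0

#: Full-task inter-stimulus interval parameters (seconds).
ISI_EXP_MEAN_S = 10.0
ISI_OFFSET_RANGE_S = (8.0, 12.0)
ISI_CAP_S = 55.0


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulus presentation.

    ``onset_time`` is in seconds from session start; ``rewarded`` marks the
    CS+ (reward delivered at ``onset_time + duration``).
    """

    onset_time: float
    modality: str
    rewarded: bool
    duration: float = STIMULUS_DURATION_S

    def __post_init__(self) -> None:
        if self.onset_time < 0:
            raise ValueError("onset_time must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def offset_time(self) -> float:
        return self.onset_time + self.duration


@dataclass
class StimulusSchedule:
    """A full session's worth of stimulus events plus reward times."""

    events: list[StimulusEvent]
    session_length: float
    task_phase: str
    cs_plus: str = "tactile"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.task_phase not in TASK_PHASES:
            raise ValueError(f"unknown task phase {self.task_phase!r}")
        if self.cs_plus not in MODALITIES:
            raise ValueError(f"unknown CS+ modality {self.cs_plus!r}")
        self.events = sorted(self.events, key=lambda e: e.onset_time)

    def onsets(self, modality: str | None = None) -> np.ndarray:
        return np.array(
            [e.onset_time for e in self.events
             if modality is None or e.modality == modality]
        )

    def offsets(self, modality: str | None = None) -> np.ndarray:
        return np.array(
            [e.offset_time for e in self.events
             if modality is None or e.modality == modality]
        )

    @property
    def reward_times(self) -> np.ndarray:
        """Reward delivery times (CS+ offsets), seconds."""
        return np.array([e.offset_time for e in self.events if e.rewarded])

    def isis(self, modality: str) -> np.ndarray:
        """Within-modality gaps from each offset to the next onset."""
        on = self.onsets(modality)
        return np.diff(on) - STIMULUS_DURATION_S if on.size > 1 else np.array([])

    def validate(self) -> None:
        for m in MODALITIES:
            on = self.onsets(m)
            off = self.offsets(m)
            if np.any(on[1:] < off[:-1]):
                raise ValueError(f"{m} events overlap within their stream")
        for e in self.events:
            if e.rewarded != (e.modality == self.cs_plus):
                raise ValueError("rewarded flag inconsistent with CS+ modality")
        if self.events and self.events[-1].offset_time > self.session_length:
            raise ValueError("events extend past session_length")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "onset_s": e.onset_time,
                "duration_s": e.duration,
                "modality": e.modality,
                "rewarded": e.rewarded,
                "reward_time_s": e.offset_time if e.rewarded else np.nan,
            }
            for e in self.events
        ]
        return pd.DataFrame(
            rows, columns=["onset_s", "duration_s", "modality", "rewarded",
                           "reward_time_s"]
        )


@dataclass
class HazardCurve:
    """Per-bin hazard of the next stimulus given survival to the bin start.

    ``hazard[i]`` is NaN where no interval survives to the bin start —
    undefined, not zero.
    """

    bin_edges: np.ndarray
    hazard: np.ndarray
    n_at_risk: np.ndarray = field(default_factory=lambda: np.array([]))

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.hazard)


def draw_full_isis(
    n: int,
    rng: np.random.Generator,
    mean_s: float = ISI_EXP_MEAN_S,
    offset_range_s: tuple[float, float] = ISI_OFFSET_RANGE_S,
    cap_s: float = ISI_CAP_S,
    round_to_s: bool = True,
) -> np.ndarray:
    """Draw full-task ISIs: Exponential + Uniform offset, clipped, binned.

    The cap clips (values above 55 s are set to 55 s, not redrawn) and
    "binned by seconds" is implemented as rounding to the nearest whole
    second.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    isis = rng.exponential(mean_s, n) + rng.uniform(*offset_range_s, n)
    np.minimum(isis, cap_s, out=isis)
    if round_to_s:
        isis = np.round(isis)
    return isis


def draw_shaping_schedule(
    n_per_modality: int,
    seed: int,
    cs_plus: str = "tactile",
) -> StimulusSchedule:
    """Balanced, randomly ordered trial schedule with Uniform(8, 12) s gaps.

    The order is a random permutation of an exactly balanced label vector
    (n tactile + n visual), not i.i.d. coin flips, so counts match exactly.
    """
    if n_per_modality < 1:
        raise ValueError("n_per_modality must be >= 1")
    rng = np.random.default_rng(seed)
    labels = np.array([MODALITIES[0]] * n_per_modality
                      + [MODALITIES[1]] * n_per_modality)
    rng.shuffle(labels)
    gaps = rng.uniform(8.0, 12.0, labels.size)
    events = []
    t = gaps[0]
    for i, mod in enumerate(labels):
        if i > 0:
            t += STIMULUS_DURATION_S + gaps[i]
        events.append(StimulusEvent(t, str(mod), rewarded=(mod == cs_plus)))
    sched = StimulusSchedule(
        events=events,
        session_length=events[-1].offset_time + 5.0,
        task_phase="shaping",
        cs_plus=cs_plus,
        seed=seed,
    )
    sched.validate()
    return sched


def draw_full_schedule(
    n_per_modality: int,
    seed: int,
    cs_plus: str = "tactile",
) -> StimulusSchedule:
    """Full-task schedule: two independent flat-hazard modality streams.

    Gaps (offset to next onset) within a stream follow
    Exponential(10 s) + Uniform(8, 12) s, clipped at 55 s and rounded to
    whole seconds; the streams may overlap. Only CS+ offsets are rewarded.
    """
    if n_per_modality < 1:
        raise ValueError("n_per_modality must be >= 1")
    rng = np.random.default_rng(seed)
    events: list[StimulusEvent] = []
    for mod in MODALITIES:
        isis = draw_full_isis(n_per_modality, rng)
        onsets = np.cumsum(isis) + STIMULUS_DURATION_S * np.arange(isis.size)
        for t in onsets:
            events.append(StimulusEvent(float(t), mod, rewarded=(mod == cs_plus)))
    session_length = max(e.offset_time for e in events) + 5.0
    sched = StimulusSchedule(
        events=events,
        session_length=session_length,
        task_phase="full",
        cs_plus=cs_plus,
        seed=seed,
    )
    sched.validate()
    return sched


def hazard_rate(isis: np.ndarray, bin_width: float = 1.0,
                max_time_s: float | None = None) -> HazardCurve:
    """Empirical hazard: P(interval ends in bin | interval >= bin start).

    Bins cover [0, max ISI] by default, or [0, ``max_time_s``] when given;
    bins with no surviving interval are NaN (undefined), never zero.
    """
    isis = np.asarray(isis, dtype=float)
    if isis.size == 0:
        raise ValueError("isis must be non-empty")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    top = isis.max() if max_time_s is None else max_time_s
    n_bins = int(np.floor(top / bin_width)) + 1
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    srt = np.sort(isis)
    below = np.searchsorted(srt, edges, side="left")
    ends = np.diff(below).astype(float)
    ends[-1] += srt.size - below[-1]  # interval exactly at the top edge
    at_risk = (srt.size - below[:-1]).astype(float)
    hazard = np.full(n_bins, np.nan)
    ok = at_risk > 0
    hazard[ok] = ends[ok] / at_risk[ok]
    return HazardCurve(bin_edges=edges, hazard=hazard, n_at_risk=at_risk)


# ---------------------------------------------------------------------------
# Schedule I/O (TSV, UTF-8, '#'-prefixed metadata header)

def write_schedule_tsv(schedule: StimulusSchedule, path,
                       extra_header: dict | None = None) -> None:
    meta = {
        "task_phase": schedule.task_phase,
        "cs_plus": schedule.cs_plus,
        "session_length_s": schedule.session_length,
        "seed": schedule.seed,
    }
    if extra_header:
        meta.update(extra_header)
    buf = io.StringIO()
    for k, v in meta.items():
        buf.write(f"# {k}={v}\n")
    schedule.to_frame().to_csv(buf, sep="\t", index=False)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_schedule_tsv(path) -> StimulusSchedule:
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    for line in lines:
        if line.startswith("#"):
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v.strip()
    df = pd.read_csv(io.StringIO("".join(lines)), sep="\t", comment="#")
    events = [
        StimulusEvent(
            float(r.onset_s), str(r.modality), bool(r.rewarded),
            float(r.duration_s),
        )
        for r in df.itertuples()
    ]
    seed = meta.get("seed")
    return StimulusSchedule(
        events=events,
        session_length=float(meta["session_length_s"]),
        task_phase=meta["task_phase"],
        cs_plus=meta.get("cs_plus", "tactile"),
        seed=None if seed in (None, "None") else int(seed),
    )
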