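"""Unit inclusion rules, region assignment, and spontaneous-rate epochs.

Putative single units are excluded as multi-unit contamination when more
than 10% of their inter-spike intervals fall below 3 ms. Units are assigned
to a thalamic region (POm, LP, VPM) by their recovered anatomical position;
units within 50 um of a region boundary are labelled "border" and excluded
from region analyses. Spontaneous firing rate is computed over quiet
epochs: stretches with no lick, stimulus, or reward for at least 2 s
beforehand and lasting at least 6 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

REFRACTORY_THRESHOLD_S = 0.003
MAX_VIOLATION_FRACTION = 0.10
BORDER_EXCLUSION_MM = 0.050


@dataclass(frozen=True)
class Box:
    """Axis-aligned box in (AP, DV, ML) millimetres."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def contains(self, p) -> bool:
        return all(self.lo[i] <= p[i] <= self.hi[i] for i in range(3))

    def boundary_distance(self, p) -> float:
        """Distance from an interior point to the nearest face."""
        return min(
            min(p[i] - self.lo[i], self.hi[i] - p[i]) for i in range(3)
        )


@dataclass
class RegionGeometry:
    """Synthetic atlas: named axis-aligned region volumes."""

    regions: dict[str, Box]

    def assign(
        self, position, border_mm: float = BORDER_EXCLUSION_MM
    ) -> tuple[str, float]:
        """Region label and distance to its boundary for one position.

        Positions inside a volume but within ``border_mm`` of its surface
        are labelled ``"border"``; positions outside every volume are
        ``"other"`` (border distance NaN).
        """
        for name, box in self.regions.items():
            if box.contains(position):
                d = box.boundary_distance(position)
                if d < border_mm:
                    return "border", d
                return name, d
        return "other", float("nan")


#: Synthetic atlas at mouse-brain scale. LP sits dorsal to POm; VPM lies lateral to
#: POm. Coordinates are (AP, DV, ML) in mm (AP negative = posterior).
DEFAULT_ATLAS = RegionGeometry(
    regions={
        "LP": Box(lo=(-2.5, 2.0, 1.0), hi=(-1.5, 2.9, 2.0)),
        "POm": Box(lo=(-2.5, 2.9, 1.0), hi=(-1.5, 3.8, 2.0)),
        "VPM": Box(lo=(-2.5, 2.9, 2.0), hi=(-1.5, 3.8, 2.6)),
    }
)


@dataclass
class UnitRecord:
    unit_id: str
    n_spikes: int
    violation_fraction: float
    qc_pass: bool
    region: str = "other"
    border_distance_mm: float = float("nan")
    spontaneous_rate_hz: float | None = None
    position: tuple[float, float, float] | None = None


def refractory_violation_fraction(
    spike_times: np.ndarray,
    threshold_s: float = REFRACTORY_THRESHOLD_S,
) -> float:
    """Fraction of inter-spike intervals shorter than the refractory limit.

    Returns NaN for fewer than two spikes (no ISIs to evaluate).
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size < 2:
        return float("nan")
    isis = np.diff(t)
    if np.any(isis < 0):
        raise ValueError("spike times must be sorted")
    return float(np.mean(isis < threshold_s))


def passes_refractory_qc(
    spike_times: np.ndarray,
    max_fraction: float = MAX_VIOLATION_FRACTION,
) -> bool:
    """True when at most ``max_fraction`` of ISIs violate the 3-ms limit.

    The exclusion rule is strict: *more than* 10% violations fails, exactly
    10% passes. Units with fewer than two spikes fail.
    """
    frac = refractory_violation_fraction(spike_times)
    if np.isnan(frac):
        return False
    return frac <= max_fraction


def quiet_epochs(
    point_events: np.ndarray,
    interval_events: np.ndarray,
    session_length: float,
    pre_quiet_s: float = 2.0,
    min_length_s: float = 6.0,
) -> list[tuple[float, float]]:
    """Maximal quiet epochs for spontaneous-rate estimation.

    An epoch qualifies if no event (lick, reward — point events; stimuli —
    occupied for their full duration) occurs within it nor in the preceding
    ``pre_quiet_s`` seconds, and it lasts at least ``min_length_s``.
    """
    occupied = [(float(t), float(t)) for t in np.atleast_1d(point_events)]
    iv = np.asarray(interval_events, dtype=float).reshape(-1, 2)
    occupied += [(float(a), float(b)) for a, b in iv]
    occupied = sorted(occupied)
    merged: list[list[float]] = []
    for a, b in occupied:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    # Free gaps between occupied blocks (plus leading/trailing stretches).
    gaps = []
    prev_end = None  # session start: nothing precedes, no 2-s buffer needed
    for a, b in merged:
        gaps.append((prev_end, a))
        prev_end = b
    gaps.append((prev_end, session_length))
    epochs = []
    for start, stop in gaps:
        lo = 0.0 if start is None else start + pre_quiet_s
        if stop - lo >= min_length_s:
            epochs.append((lo, float(stop)))
    return epochs


def spontaneous_rate(
    spike_times: np.ndarray,
    epochs: list[tuple[float, float]],
) -> float | None:
    """Mean firing rate over quiet epochs; None when no epoch qualifies."""
    if not epochs:
        return None
    t = np.asarray(spike_times, dtype=float)
    total_dur = sum(b - a for a, b in epochs)
    n = sum(int(np.count_nonzero((t >= a) & (t < b))) for a, b in epochs)
    return n / total_dur


def session_quiet_epochs(schedule, lick_times, **kwargs) -> list[tuple[float, float]]:
    """Quiet epochs from a schedule (stimuli + rewards) and lick times."""
    onsets = schedule.onsets()
    offsets = schedule.offsets()
    intervals = np.column_stack([onsets, offsets]) if onsets.size else np.empty((0, 2))
    points = np.concatenate([np.asarray(lick_times, float), schedule.reward_times])
    return quiet_epochs(points, intervals, schedule.session_length, **kwargs)
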