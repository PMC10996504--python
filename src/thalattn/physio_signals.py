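"""Conditioning of pupil and whisker signals, and common-rate alignment.

Pupil radius (60 fps video) is smoothed over 5 frames and blink artifacts —
excursions from a 3-s running median — are removed and linearly
interpolated. The whisker mean angle (125 fps) is band-passed 4–30 Hz
(zero-phase Butterworth) and passed through a Hilbert transform; the
instantaneous phase identifies the most protracted (phase 0) and most
retracted (phase ±π) sample of each whisk cycle, and whisking amplitude is
the difference between envelopes anchored at those samples on the
*unfiltered* angle. Finally, all continuous traces are linearly
interpolated onto a shared 1-kHz clock and event times rounded to 1 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.ndimage import median_filter, uniform_filter1d


class TraceRejectedError(ValueError):
    """Raised when a trace fails quality control (e.g. mostly blinks)."""


@dataclass
class FixedRateTrace:
    """A regularly sampled signal: values at ``sample_rate`` Hz from
    ``start_time`` seconds."""

    values: np.ndarray
    sample_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.values = np.asarray(self.values, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.values.size) / self.sample_rate

    @property
    def duration(self) -> float:
        return self.values.size / self.sample_rate

    @property
    def end_time(self) -> float:
        return self.start_time + (self.values.size - 1) / self.sample_rate


@dataclass
class WhiskDecomposition:
    """Band-passed whisker angle with Hilbert phase and cycle envelopes."""

    filtered_angle: FixedRateTrace
    phase: np.ndarray
    protracted_envelope: np.ndarray
    retracted_envelope: np.ndarray
    amplitude: FixedRateTrace
    protracted_idx: np.ndarray = field(default_factory=lambda: np.array([], int))
    retracted_idx: np.ndarray = field(default_factory=lambda: np.array([], int))


@dataclass
class AlignedBundle:
    """Continuous traces on a shared 1-kHz grid plus ms-rounded events."""

    traces: dict[str, np.ndarray]
    events: dict[str, np.ndarray]
    sample_rate: float
    start_time: float

    @property
    def n_samples(self) -> int:
        return next(iter(self.traces.values())).size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


def pupil_radius_from_ellipse(semi_major, semi_minor):
    """Pupil radius as the geometric mean of the ellipse semi-axes."""
    a = np.asarray(semi_major, dtype=float)
    b = np.asarray(semi_minor, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("ellipse semi-axes must be positive")
    return np.sqrt(a * b)


def clean_pupil_trace(
    raw: FixedRateTrace,
    smooth_frames: int = 5,
    median_window_s: float = 3.0,
    deviation_fraction: float = 0.25,
    max_excluded_fraction: float = 0.5,
) -> FixedRateTrace:
    """Smooth a pupil-radius trace and interpolate across blink artifacts.

    Samples whose deviation from a ``median_window_s`` running median
    exceeds ``deviation_fraction`` of the local median are treated as
    blinks and replaced by linear interpolation; the blink test runs on the
    raw trace (before smoothing) so artifacts cannot leak into their
    neighbours through the moving average. A ``smooth_frames``-frame moving
    average is then applied. If more than ``max_excluded_fraction`` of
    samples are excluded the trace is rejected.
    """
    x = np.asarray(raw.values, dtype=float)
    win = int(round(median_window_s * raw.sample_rate))
    win += 1 - win % 2  # odd window
    med = median_filter(x, size=win, mode="nearest")
    bad = np.abs(x - med) > deviation_fraction * np.abs(med)
    frac = bad.mean()
    if frac > max_excluded_fraction:
        raise TraceRejectedError(
            f"{frac:.0%} of samples deviate from the running median "
            f"(limit {max_excluded_fraction:.0%}); trace rejected"
        )
    if bad.any():
        good = ~bad
        idx = np.arange(x.size)
        x = x.copy()
        x[bad] = np.interp(idx[bad], idx[good], x[good])
    x = uniform_filter1d(x, size=smooth_frames, mode="nearest")
    return FixedRateTrace(x, raw.sample_rate, raw.start_time)


def _phase_anchor_indices(phase: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Samples nearest phase 0 (protraction) and ±π wraps (retraction)."""
    d = np.diff(phase)
    # Zero crossings of a monotonically advancing phase: sign change without
    # the ±π wrap discontinuity.
    zero = np.nonzero((phase[:-1] < 0) & (phase[1:] >= 0) & (np.abs(d) < np.pi))[0]
    prot = np.where(np.abs(phase[zero + 1]) < np.abs(phase[zero]), zero + 1, zero)
    wrap = np.nonzero(d < -np.pi)[0]
    retr = np.where(np.pi - phase[wrap] < phase[wrap + 1] + np.pi, wrap, wrap + 1)
    return np.unique(prot), np.unique(retr)


def whisk_amplitude(
    angle: FixedRateTrace,
    band_hz: tuple[float, float] = (4.0, 30.0),
    order: int = 4,
) -> WhiskDecomposition:
    """Whisking amplitude from the Hilbert phase of the band-passed angle.

    Envelope anchors take the *unfiltered* angle at the protracted /
    retracted samples of each whisk cycle, are linearly interpolated to the
    full rate (held constant beyond the first/last anchor), and amplitude is
    protracted − retracted envelope, floored at zero.
    """
    if angle.duration <= 1.0:
        raise ValueError("whisker-angle trace must be longer than 1 s")
    fs = angle.sample_rate
    if fs <= 2 * band_hz[1]:
        raise ValueError("sample rate too low for the requested band")
    sos = signal.butter(order, band_hz, btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, angle.values)
    phase = np.angle(signal.hilbert(filt))
    prot_idx, retr_idx = _phase_anchor_indices(phase)
    n = angle.values.size
    idx = np.arange(n)
    raw = angle.values
    if prot_idx.size == 0 or retr_idx.size == 0:
        upper = np.full(n, raw.mean())
        lower = np.full(n, raw.mean())
    else:
        upper = np.interp(idx, prot_idx, raw[prot_idx])
        lower = np.interp(idx, retr_idx, raw[retr_idx])
    amp = np.maximum(upper - lower, 0.0)
    return WhiskDecomposition(
        filtered_angle=FixedRateTrace(filt, fs, angle.start_time),
        phase=phase,
        protracted_envelope=upper,
        retracted_envelope=lower,
        amplitude=FixedRateTrace(amp, fs, angle.start_time),
        protracted_idx=prot_idx,
        retracted_idx=retr_idx,
    )


def resample_to_common_rate(
    traces: dict[str, FixedRateTrace],
    events: dict[str, np.ndarray] | None = None,
    target_rate: float = 1000.0,
) -> AlignedBundle:
    """Linearly interpolate traces to a shared grid; round events to 1 ms."""
    if not traces:
        raise ValueError("at least one trace is required")
    t0 = max(tr.start_time for tr in traces.values())
    t1 = min(tr.end_time for tr in traces.values())
    if t1 <= t0:
        raise ValueError("traces have disjoint time supports")
    dt = 1.0 / target_rate
    grid = t0 + np.arange(int(np.floor((t1 - t0) / dt)) + 1) * dt
    out = {
        name: np.interp(grid, tr.times, tr.values)
        for name, tr in traces.items()
    }
    ev = {
        name: np.round(np.asarray(times, dtype=float) / dt) * dt
        for name, times in (events or {}).items()
    }
    return AlignedBundle(traces=out, events=ev, sample_rate=target_rate,
                         start_time=t0)


# ---------------------------------------------------------------------------
# Trace I/O: CSV with `rate_hz` / `start_s` header rows, one value per line.

def write_trace_csv(trace: FixedRateTrace, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"rate_hz,{trace.sample_rate!r}\n")
        fh.write(f"start_s,{trace.start_time!r}\n")
        for v in trace.values:
            fh.write(f"{float(v)!r}\n")


def read_trace_csv(path) -> FixedRateTrace:
    with open(path, encoding="utf-8") as fh:
        rate = float(fh.readline().split(",")[1])
        start = float(fh.readline().split(",")[1])
        values = np.array([float(line) for line in fh if line.strip()])
    return FixedRateTrace(values, rate, start)
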