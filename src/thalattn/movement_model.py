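"""Movement/arousal regression of firing rates and cross-correlations.

Firing rates, lick rate, whisking amplitude, and pupil radius are binned
into a shared 250-ms grid. For each unit an ordinary least-squares model
predicts binned firing rate from whisking amplitude, pupil radius, and
lick rate (plus an intercept — the baseline term). The model residuals are
a baseline-subtracted, movement-corrected firing rate: stimulus-aligned
structure that survives in the residuals cannot be attributed to the
movement variables.

Cross-correlations between a unit's binned rate and a lag-shifted movement
variable use the convention that negative lags mean the unit's activity
precedes the movement variable and positive lags that it follows it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .physio_signals import FixedRateTrace

logger = logging.getLogger(__name__)

DEFAULT_BIN_S = 0.25
PREDICTOR_NAMES = ("whisk", "pupil", "lick")


@dataclass
class BinnedSession:
    """All session series on one bin grid (rates in Hz)."""

    bin_width: float
    start_time: float
    bin_starts: np.ndarray
    rates: dict[str, np.ndarray]        # unit_id -> Hz per bin
    predictors: dict[str, np.ndarray]   # whisk, pupil, lick

    @property
    def n_bins(self) -> int:
        return self.bin_starts.size


@dataclass
class MovementFit:
    unit_id: str
    intercept: float
    coefficients: dict[str, float]      # original predictor scale
    dropped: list[str]
    residuals: np.ndarray
    r2: float


@dataclass
class Psth:
    time_rel: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_trials: int = 0


def bin_session(
    duration: float,
    spikes: dict[str, np.ndarray],
    lick_times: np.ndarray,
    traces: dict[str, FixedRateTrace],
    bin_width: float = DEFAULT_BIN_S,
    start_time: float = 0.0,
) -> BinnedSession:
    """Bin spike, lick, and continuous series onto one grid.

    Spike and lick counts are converted to Hz; continuous traces are
    averaged per bin. A final partial bin is dropped (and logged).
    """
    n_bins = int(np.floor((duration - start_time) / bin_width))
    if n_bins < 1:
        raise ValueError("session shorter than one bin")
    if (duration - start_time) - n_bins * bin_width > 1e-9:
        logger.info("dropping final partial bin (%.3f s)",
                    (duration - start_time) - n_bins * bin_width)
    edges = start_time + np.arange(n_bins + 1) * bin_width
    starts = edges[:-1]
    rates = {
        uid: np.histogram(t, bins=edges)[0] / bin_width
        for uid, t in spikes.items()
    }
    predictors: dict[str, np.ndarray] = {}
    predictors["lick"] = np.histogram(lick_times, bins=edges)[0] / bin_width
    for name, tr in traces.items():
        idx = np.floor((tr.times - start_time) / bin_width).astype(int)
        ok = (idx >= 0) & (idx < n_bins)
        sums = np.bincount(idx[ok], weights=tr.values[ok], minlength=n_bins)
        counts = np.bincount(idx[ok], minlength=n_bins)
        with np.errstate(invalid="ignore"):
            mean = sums / counts
        predictors[name] = mean
    return BinnedSession(
        bin_width=bin_width,
        start_time=start_time,
        bin_starts=starts,
        rates=rates,
        predictors=predictors,
    )


def fit_movement_model(
    binned: BinnedSession,
    unit_id: str,
    predictor_names: tuple[str, ...] = PREDICTOR_NAMES,
) -> MovementFit:
    """OLS of one unit's binned rate on the movement predictors.

    Predictors are standardized internally for conditioning; coefficients
    are reported on the original scale. Constant predictors are dropped
    from the design (logged). Requires at least 100 bins.
    """
    y = binned.rates[unit_id]
    if y.size < 100:
        raise ValueError("at least 100 bins are required for the fit")
    cols, names, dropped = [], [], []
    for name in predictor_names:
        x = binned.predictors[name]
        if np.ptp(x) == 0 or not np.all(np.isfinite(x)):
            dropped.append(name)
            logger.info("unit %s: predictor %s constant/invalid, dropped",
                        unit_id, name)
            continue
        cols.append(x)
        names.append(name)
    if cols:
        X = np.column_stack(cols)
        mu, sigma = X.mean(axis=0), X.std(axis=0)
        Xs = np.column_stack([np.ones(y.size), (X - mu) / sigma])
        beta, *_ = np.linalg.lstsq(Xs, y, rcond=None)
        yhat = Xs @ beta
        slopes = beta[1:] / sigma
        intercept = float(beta[0] - np.sum(slopes * mu))
    else:
        yhat = np.full(y.size, y.mean())
        slopes = np.array([])
        intercept = float(y.mean())
    resid = y - yhat
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 0.0 if ss_tot == 0 else float(1.0 - np.sum(resid**2) / ss_tot)
    coefs = {name: float(s) for name, s in zip(names, slopes)}
    for name in dropped:
        coefs[name] = float("nan")
    return MovementFit(
        unit_id=unit_id,
        intercept=intercept,
        coefficients=coefs,
        dropped=dropped,
        residuals=resid,
        r2=r2,
    )


def event_aligned_series(
    series: np.ndarray,
    binned: BinnedSession,
    event_times: np.ndarray,
    window_s: tuple[float, float] = (-2.0, 4.0),
) -> Psth:
    """Cut a per-bin series around events and average over events.

    Events whose window runs past either end of the session are skipped.
    """
    bw = binned.bin_width
    rel = np.arange(int(np.floor(window_s[0] / bw)),
                    int(np.ceil(window_s[1] / bw)))
    segs = []
    for t in np.atleast_1d(event_times):
        base = int(np.round((t - binned.start_time) / bw))
        idx = base + rel
        if idx[0] < 0 or idx[-1] >= series.size:
            continue
        segs.append(series[idx])
    if not segs:
        logger.warning("no events with a complete peri-event window")
        return Psth(time_rel=rel * bw, mean=np.full(rel.size, np.nan),
                    sem=np.full(rel.size, np.nan), n_trials=0)
    arr = np.array(segs)
    return Psth(
        time_rel=rel * bw,
        mean=arr.mean(axis=0),
        sem=arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
        if arr.shape[0] > 1 else np.zeros(rel.size),
        n_trials=arr.shape[0],
    )


def residual_psth(
    fit: MovementFit,
    binned: BinnedSession,
    event_times: np.ndarray,
    window_s: tuple[float, float] = (-2.0, 4.0),
) -> Psth:
    """Event-aligned mean +/- SEM of a unit's movement-corrected rate."""
    return event_aligned_series(fit.residuals, binned, event_times, window_s)


def firing_behavior_xcorr(
    rate: np.ndarray,
    predictor: np.ndarray,
    bin_width: float,
    max_lag_s: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of a unit's rate with a lag-shifted predictor.

    Returns (lags in seconds, correlations). At lag L the unit's rate at
    time t is correlated with the predictor at t - L, so a peak at positive
    L means activity follows the movement variable by L seconds and a peak
    at negative L that activity precedes it.
    """
    rate = np.asarray(rate, float)
    predictor = np.asarray(predictor, float)
    if rate.size != predictor.size:
        raise ValueError("series lengths differ")
    max_k = int(round(max_lag_s / bin_width))
    if rate.size <= 2 * max_k:
        raise ValueError("series too short for the requested maximum lag")
    lags = np.arange(-max_k, max_k + 1)
    corr = np.full(lags.size, np.nan)
    for j, k in enumerate(lags):
        if k > 0:
            a, b = rate[k:], predictor[:-k]
        elif k < 0:
            a, b = rate[:k], predictor[-k:]
        else:
            a, b = rate, predictor
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            continue
        corr[j] = np.corrcoef(a, b)[0, 1]
    return lags * bin_width, corr
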