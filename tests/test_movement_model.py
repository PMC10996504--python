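import numpy as np
import pytest

from thalattn.movement_model import (
    BinnedSession,
    bin_session,
    event_aligned_series,
    firing_behavior_xcorr,
    fit_movement_model,
    residual_psth,
)
from thalattn.physio_signals import FixedRateTrace


def _binned_from_arrays(rate, predictors, bw=0.25):
    n = rate.size
    return BinnedSession(
        bin_width=bw, start_time=0.0,
        bin_starts=np.arange(n) * bw,
        rates={"u": rate},
        predictors=predictors,
    )


class TestBinning:
    def test_homogeneous_unit_rate_preserved(self, rng):
        T = 200.0
        spk = np.sort(rng.uniform(0, T, rng.poisson(10 * T)))
        binned = bin_session(T, {"u": spk}, np.empty(0), {})
        assert binned.rates["u"].mean() == pytest.approx(10.0, abs=0.5)

    def test_single_lick_rate_conversion(self):
        binned = bin_session(10.0, {"u": np.empty(0)}, np.array([2.1]), {})
        lick = binned.predictors["lick"]
        assert lick[int(2.1 / 0.25)] == pytest.approx(4.0)
        assert lick.sum() == pytest.approx(4.0)

    def test_constant_trace_stays_constant(self):
        tr = FixedRateTrace(np.full(1250, 7.5), 125.0)
        binned = bin_session(10.0, {"u": np.empty(0)}, np.empty(0),
                             {"whisk": tr})
        assert np.allclose(binned.predictors["whisk"], 7.5)

    def test_partial_final_bin_dropped(self):
        binned = bin_session(10.1, {"u": np.empty(0)}, np.empty(0), {})
        assert binned.n_bins == 40


class TestMovementFit:
    def _predictors(self, rng, n=2000):
        return {
            "whisk": rng.uniform(5, 25, n),
            "pupil": rng.uniform(15, 25, n),
            "lick": rng.poisson(1.0, n).astype(float),
        }

    def test_known_coefficients_recovered(self, rng):
        pred = self._predictors(rng)
        y = 3.0 + 2.0 * pred["whisk"] + 0.5 * pred["pupil"] \
            + rng.normal(0, 1.0, 2000)
        fit = fit_movement_model(_binned_from_arrays(y, pred), "u")
        assert fit.coefficients["whisk"] == pytest.approx(2.0, abs=0.05)
        assert fit.coefficients["pupil"] == pytest.approx(0.5, abs=0.05)
        assert fit.coefficients["lick"] == pytest.approx(0.0, abs=0.1)
        assert fit.intercept == pytest.approx(3.0, abs=1.5)

    def test_exact_linear_relation_leaves_zero_residuals(self, rng):
        pred = self._predictors(rng)
        y = 1.0 + 0.7 * pred["whisk"] - 0.2 * pred["lick"]
        fit = fit_movement_model(_binned_from_arrays(y, pred), "u")
        assert np.max(np.abs(fit.residuals)) < 1e-8
        assert fit.r2 == pytest.approx(1.0)

    def test_coupling_free_unit_flat_fit(self, rng):
        pred = self._predictors(rng)
        y = rng.normal(10.0, 1.0, 2000)
        fit = fit_movement_model(_binned_from_arrays(y, pred), "u")
        assert abs(fit.coefficients["whisk"]) < 0.05
        assert fit.r2 < 0.01

    def test_residuals_orthogonal_to_predictors_and_centered(self, rng):
        pred = self._predictors(rng)
        y = 2.0 + 1.5 * pred["whisk"] + rng.normal(0, 2.0, 2000)
        fit = fit_movement_model(_binned_from_arrays(y, pred), "u")
        assert abs(fit.residuals.mean()) < 1e-9
        for x in pred.values():
            xc = x - x.mean()
            assert abs(np.dot(fit.residuals, xc)) / np.linalg.norm(xc) < 1e-6

    def test_constant_predictor_dropped(self, rng):
        pred = self._predictors(rng)
        pred["pupil"] = np.full(2000, 20.0)
        y = rng.normal(10.0, 1.0, 2000)
        fit = fit_movement_model(_binned_from_arrays(y, pred), "u")
        assert "pupil" in fit.dropped
        assert np.isnan(fit.coefficients["pupil"])

    def test_r2_never_decreases_with_added_predictor(self, rng):
        pred = self._predictors(rng)
        y = 5.0 + 1.0 * pred["whisk"] + 0.3 * pred["pupil"] \
            + rng.normal(0, 1.0, 2000)
        binned = _binned_from_arrays(y, pred)
        r2 = [fit_movement_model(binned, "u", predictor_names=names).r2
              for names in (("whisk",), ("whisk", "pupil"),
                            ("whisk", "pupil", "lick"))]
        assert r2[0] <= r2[1] + 1e-12
        assert r2[1] <= r2[2] + 1e-12

    def test_too_few_bins_rejected(self, rng):
        pred = {k: v[:50] for k, v in self._predictors(rng).items()}
        with pytest.raises(ValueError):
            fit_movement_model(_binned_from_arrays(np.ones(50), pred), "u")


class TestXcorr:
    def test_delayed_copy_peaks_at_positive_lag(self, rng):
        bw = 0.1
        pupil = rng.standard_normal(5000)
        rate = np.roll(pupil, 10)  # rate follows pupil by 1 s
        lags, corr = firing_behavior_xcorr(rate, pupil, bw, max_lag_s=3.0)
        assert lags[int(np.nanargmax(corr))] == pytest.approx(1.0)

    def test_negated_predictor_anticorrelated_at_zero_lag(self, rng):
        whisk = rng.standard_normal(2000)
        lags, corr = firing_behavior_xcorr(-whisk, whisk, 0.1)
        assert corr[lags == 0.0][0] == pytest.approx(-1.0)

    def test_autocorrelation_peaks_at_zero_with_unit_value(self, rng):
        x = rng.standard_normal(3000)
        lags, corr = firing_behavior_xcorr(x, x, 0.1)
        assert corr[lags == 0.0][0] == pytest.approx(1.0)
        assert lags[int(np.nanargmax(corr))] == 0.0

    def test_independent_series_near_zero(self, rng):
        a, b = rng.standard_normal(5000), rng.standard_normal(5000)
        _, corr = firing_behavior_xcorr(a, b, 0.1)
        assert np.nanmax(np.abs(corr)) < 5.0 / np.sqrt(5000)

    def test_zero_variance_series_undefined(self, rng):
        _, corr = firing_behavior_xcorr(np.ones(1000),
                                        rng.standard_normal(1000), 0.1)
        assert np.all(np.isnan(corr))


class TestResidualPsth:
    def test_zero_residual_unit_flat_psth(self):
        binned = _binned_from_arrays(np.zeros(400), {})
        psth = event_aligned_series(np.zeros(400), binned,
                                    np.array([20.0, 40.0, 60.0]))
        assert psth.n_trials == 3
        assert np.allclose(psth.mean, 0.0)

    def test_events_near_edges_skipped(self):
        binned = _binned_from_arrays(np.zeros(400), {})
        psth = event_aligned_series(np.zeros(400), binned,
                                    np.array([0.5, 50.0, 99.9]))
        assert psth.n_trials == 1
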