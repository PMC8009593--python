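"""Analysis pipeline: baselines, integrals, fits, detection limits, A/T."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aequosim import (
    AequorinPool,
    DetectorConfig,
    EmissionProfile,
    QdcConfig,
    Series,
    apply_deadtime,
    baseline_subtract,
    block_average,
    count_windows,
    discharge_ratio,
    emit,
    exclude_highest,
    exclude_lowest,
    fit_loglog,
    integrate_gates,
    integrated_intensity,
    lod_analytic,
    lod_empirical,
    peak_frequency,
    sample_arrivals,
    scenario_lysate,
    sensitivity_ratio,
)
from aequosim._rng import substream
from aequosim.spc_channel import ArrivalStream, CountTrace


def _count_trace(counts, window=0.1):
    counts = np.asarray(counts, dtype=np.int64)
    return CountTrace(t0=0.0, window=window, counts=counts,
                      saturated=np.zeros(len(counts), dtype=bool))


class TestBaselineSubtract:
    def test_constant_trace_becomes_zero(self):
        ser = baseline_subtract(_count_trace([50] * 30), (0.0, 3.0))
        np.testing.assert_allclose(ser.values, 0.0)
        assert ser.baseline == pytest.approx(500.0)

    def test_known_offset_removed(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(1000, 200)
        tr = _count_trace(counts)
        ser = baseline_subtract(tr, (0.0, 10.0))
        window_mean_se = np.sqrt(1000 / 100) / 0.1
        assert abs(ser.values[:100].mean()) < 1e-9  # exact on its own window
        assert abs(ser.baseline - 1e4) < 3 * window_mean_se

    def test_dark_trace_residual_mean_near_zero(self):
        det = DetectorConfig(dcr=904e3)
        prof = EmissionProfile.zero(30.0, 1e-3)
        stream = sample_arrivals(prof, det, mode="binned", rng=substream(30, "bl"))
        trace = count_windows(stream, 0.1)
        ser = baseline_subtract(trace, (0.0, 15.0))
        se = np.sqrt(904e3 / 0.1) / np.sqrt(150) * np.sqrt(2)
        assert abs(ser.values[150:].mean()) < 3 * se

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            baseline_subtract(_count_trace([1] * 30), (0.0, 0.5))


class TestIntegratedIntensity:
    def test_zero_trace(self):
        ser = baseline_subtract(_count_trace([0] * 20), (0.0, 2.0))
        assert integrated_intensity(ser, (0.0, 2.0)) == 0.0

    def test_doubled_pool_doubles_integral(self):
        det = DetectorConfig(dcr=0.0)
        scen = scenario_lysate(baseline_s=2.0, duration=12.0, dt=0.01)
        ints = []
        for i, n in enumerate((1e5, 2e5)):
            prof = emit(AequorinPool(n, lambda_max=0.5), scen)
            stream = sample_arrivals(prof, det, mode="binned",
                                     rng=substream(31, f"d{i}"))
            trace = count_windows(apply_deadtime(stream, det,
                                                 rng=substream(31, f"dd{i}")), 0.1)
            ser = baseline_subtract(trace, (0.0, 2.0))
            ints.append(integrated_intensity(ser, (2.0, 12.0)))
        se = np.sqrt(2e5 + 4 * 1e5)
        assert abs(ints[1] - 2 * ints[0]) < 3 * se

    def test_window_outside_trace_rejected(self):
        ser = baseline_subtract(_count_trace([0] * 20), (0.0, 2.0))
        with pytest.raises(ValueError):
            integrated_intensity(ser, (10.0, 20.0))

    def test_spc_ci_cross_branch_consistency(self):
        """Sub-pile-up: both branches recover the same integral within 5 %.

        Dark counts also occupy the discriminator, so the sub-pile-up regime
        requires a low total rate: at the full 904 kHz dark level the counting
        branch loses ~5 % of any signal to dark-induced pulse overlap.
        """
        det = DetectorConfig(dcr=100e3)
        qdc = QdcConfig()
        pool = AequorinPool(5e6, lambda_max=0.1)  # peak 500 kHz
        scen = scenario_lysate(baseline_s=10.0, duration=50.0, dt=0.01)
        prof = emit(pool, scen)
        stream = sample_arrivals(prof, det, mode="binned", rng=substream(32, "s"))
        trace = count_windows(apply_deadtime(stream, det, rng=substream(32, "sd")), 0.1)
        spc = integrated_intensity(baseline_subtract(trace, (0, 10)), (10, 50))
        ct = block_average(integrate_gates(prof, det, qdc, rng=substream(32, "c")), 560)
        ci = integrated_intensity(baseline_subtract(ct, (0, 10)), (10, 50))
        assert abs(spc - ci) / ci < 0.05


class TestPeakFrequency:
    def test_deterministic_maximum(self):
        counts = [0, 10, 20, 30, 20, 10, 0]
        ser = baseline_subtract(_count_trace([0] * 10 + counts + [0] * 10), (0, 1))
        peak, t_peak = peak_frequency(ser, smooth=1)
        assert peak == pytest.approx(300.0)
        assert t_peak == pytest.approx(1.3)
        smoothed, _ = peak_frequency(ser)  # default smoother never overshoots
        assert smoothed <= peak

    def test_zero_trace_zero_peak(self):
        ser = baseline_subtract(_count_trace([0] * 20), (0, 2))
        assert peak_frequency(ser)[0] == 0.0

    def test_empty_trace_rejected(self):
        ser = Series(t=np.array([]), values=np.array([]), dt=0.1,
                     kind="spc", baseline=0.0)
        with pytest.raises(ValueError):
            peak_frequency(ser)


class TestFitLoglog:
    def test_exact_power_law_recovery(self):
        factors = 2.0 ** -np.arange(12)
        m, a = 3.5e6, 1.25
        res = fit_loglog(factors, m * factors ** a)
        assert res.slope == pytest.approx(a, abs=1e-12)
        assert res.intercept == pytest.approx(np.log2(m), abs=1e-10)
        np.testing.assert_allclose(res.residuals, 0.0, atol=1e-10)

    def test_exclusion_presets(self):
        factors = 2.0 ** -np.arange(12)
        assert set(exclude_lowest(factors, 3)) == {9, 10, 11}
        assert set(exclude_highest(factors, 3)) == {0, 1, 2}

    def test_non_positive_included_integral_rejected(self):
        factors = [1.0, 0.5, 0.25, 0.125]
        with pytest.raises(ValueError, match="non-positive"):
            fit_loglog(factors, [8, 4, -1, 1])
        # fine once the offending point is excluded
        res = fit_loglog(factors, [8, 4, -1, 1], excluded=(2,))
        assert res.n_used == 3

    def test_confidence_interval_covers_unit_slope(self):
        """95 % CI on the slope covers 1.0 in >= 90 % of seeded replicates."""
        from scipy.stats import t as t_dist

        rng = np.random.default_rng(1234)
        factors = 2.0 ** -np.arange(12)
        n_top = 2e4
        covered = 0
        n_rep = 50
        for _ in range(n_rep):
            # linear response with constant relative measurement noise
            y = n_top * factors * np.exp(rng.normal(0.0, 0.1, factors.size))
            res = fit_loglog(factors, y)
            tq = t_dist.ppf(0.975, res.n_used - 2)
            lo, hi = res.slope - tq * res.slope_se, res.slope + tq * res.slope_se
            covered += lo <= 1.0 <= hi
        assert covered >= 0.9 * n_rep


class TestSensitivityRatio:
    def test_printed_intercepts(self):
        assert round(sensitivity_ratio(17.90, 17.09), 2) == 1.75

    def test_identities(self):
        assert sensitivity_ratio(5.0, 5.0) == 1.0
        assert sensitivity_ratio(6.0, 5.0) == 2.0


class TestLodAnalytic:
    def test_reference_values(self):
        assert lod_analytic(904e3, 0.1).lod_hz == pytest.approx(9.02e3, rel=1e-3)
        assert lod_analytic(904e3, 5e-6).lod_hz == pytest.approx(1.2756e6, rel=1e-3)
        assert lod_analytic(0.0, 0.1).lod_hz == 0.0

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        dcr=st.floats(min_value=1e3, max_value=1e7),
        dt=st.floats(min_value=1e-6, max_value=1.0),
        k=st.floats(min_value=1.1, max_value=100.0),
    )
    def test_scaling_laws(self, dcr, dt, k):
        base = lod_analytic(dcr, dt).lod_hz
        assert lod_analytic(dcr, dt / k).lod_hz == pytest.approx(
            base * np.sqrt(k), rel=1e-9
        )
        assert lod_analytic(dcr * k, dt).lod_hz == pytest.approx(
            base * np.sqrt(k), rel=1e-9
        )


class TestLodEmpirical:
    def test_spc_agrees_with_analytic(self):
        det = DetectorConfig(dcr=904e3)
        prof = EmissionProfile.zero(50.0, 1e-3)
        stream = sample_arrivals(prof, det, mode="binned", rng=substream(33, "lod"))
        trace = count_windows(stream, 0.1)
        res = lod_empirical(trace)
        assert res.lod_hz == pytest.approx(lod_analytic(904e3, 0.1).lod_hz, rel=0.15)

    def test_ci_poisson_only_agrees_with_analytic(self):
        det = DetectorConfig(dcr=904e3)
        qdc = QdcConfig(noise_sigma=0.0)
        prof = EmissionProfile.zero(2.0, 1e-3)
        trace = integrate_gates(prof, det, qdc, rng=substream(34, "lodci"))
        res = lod_empirical(trace)
        assert res.lod_hz == pytest.approx(lod_analytic(904e3, 5e-6).lod_hz, rel=0.15)

    def test_block_averaging_improves_sqrt_block(self):
        det = DetectorConfig(dcr=904e3)
        qdc = QdcConfig()  # white electronic noise on
        block, n_blocks = 100, 200
        prof = EmissionProfile.zero(block * n_blocks / qdc.sampling_rate + 1e-3, 1e-3)
        trace = integrate_gates(prof, det, qdc, rng=substream(35, "blk"))
        raw = lod_empirical(trace)
        avg = lod_empirical(block_average(trace, block))
        assert raw.lod_hz / avg.lod_hz == pytest.approx(np.sqrt(block), rel=0.15)

    def test_short_dark_trace_rejected(self):
        with pytest.raises(ValueError, match="100"):
            lod_empirical(_count_trace([90000] * 50))


class TestDischargeRatio:
    def test_windows_must_be_disjoint(self):
        ser = baseline_subtract(_count_trace([10] * 100), (0.0, 2.0))
        with pytest.raises(ValueError, match="disjoint"):
            discharge_ratio(ser, (2.0, 6.0), (5.0, 9.0))

    def test_nonpositive_lysis_integral_rejected(self):
        ser = baseline_subtract(_count_trace([10] * 100), (0.0, 9.0))
        with pytest.raises(ValueError, match="positive"):
            discharge_ratio(ser, (2.0, 4.0), (5.0, 9.0))

    def test_known_ratio_recovered(self):
        counts = [0] * 20 + [100] * 10 + [0] * 10 + [400] * 10 + [0] * 10
        ser = baseline_subtract(_count_trace(counts), (0.0, 2.0))
        res = discharge_ratio(ser, (2.0, 4.0), (4.0, 6.0))
        assert res.ratio == pytest.approx(0.25)
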