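"""Counting branch: Poisson sampling, dead-time losses, windowed counting."""

import numpy as np
import pytest

from aequosim import (
    ArrivalStream,
    DetectorConfig,
    EmissionProfile,
    apply_deadtime,
    count_windows,
    expected_counted_rate,
    pileup_probability,
    sample_arrivals,
)
from aequosim._rng import substream
from aequosim.spc_channel import read_count_trace, write_count_trace


class TestSampleArrivals:
    def test_constant_rate_poisson_mean(self, const_profile):
        det = DetectorConfig(dcr=0.0)
        prof = const_profile(1e6, 1.0, 1e-3)
        stream = sample_arrivals(prof, det, mode="events", rng=substream(0, "t"))
        assert abs(stream.n_events - 1e6) < 3 * np.sqrt(1e6)
        assert np.all(np.diff(stream.times) >= 0)

    def test_dark_only_rate(self):
        det = DetectorConfig(dcr=904e3)
        prof = EmissionProfile.zero(1.0, 1e-3)
        stream = sample_arrivals(prof, det, mode="binned", rng=substream(1, "t"))
        assert abs(stream.n_events - 904e3) < 3 * np.sqrt(904e3)

    def test_no_signal_no_dark_is_empty(self):
        det = DetectorConfig(dcr=0.0)
        prof = EmissionProfile.zero(1.0, 1e-3)
        stream = sample_arrivals(prof, det, mode="events", rng=substream(2, "t"))
        assert stream.n_events == 0

    def test_deterministic_given_seed(self, const_profile):
        det = DetectorConfig(dcr=1e4)
        prof = const_profile(1e4, 0.5, 1e-3)
        s1 = sample_arrivals(prof, det, mode="events", rng=substream(5, "x"))
        s2 = sample_arrivals(prof, det, mode="events", rng=substream(5, "x"))
        np.testing.assert_array_equal(s1.times, s2.times)

    def test_auto_mode_switches_on_rate(self, const_profile):
        det = DetectorConfig(dcr=0.0, hybrid_threshold_hz=5e6)
        lo = sample_arrivals(const_profile(1e5, 0.1, 1e-3), det, rng=substream(6, "a"))
        hi = sample_arrivals(const_profile(1e7, 0.1, 1e-3), det, rng=substream(6, "b"))
        assert lo.mode == "events"
        assert hi.mode == "binned"

    def test_hybrid_modes_agree_in_distribution(self, const_profile):
        """Event-level and binned simulation give compatible window rates."""
        det = DetectorConfig(dcr=0.0)
        prof = const_profile(2e6, 1.0, 1e-3)
        f = []
        for mode, label in (("events", "ev"), ("binned", "bin")):
            stream = sample_arrivals(prof, det, mode=mode,
                                     rng=substream(7, label))
            f.append(count_windows(stream, 0.1).freq)
        se = np.sqrt(2e6 / 0.1 / len(f[0]))  # per-mode SE of the mean rate
        assert abs(f[0].mean() - f[1].mean()) < 3 * np.sqrt(2) * se


class TestDeadtime:
    def test_negligible_tau_is_identity(self):
        det = DetectorConfig(pulse_tau=1e-15)
        times = np.sort(np.random.default_rng(0).random(1000))
        stream = ArrivalStream(mode="events", span=(0, 1), times=times)
        out = apply_deadtime(stream, det)
        np.testing.assert_array_equal(out.times, times)

    def test_event_within_dead_time_dropped(self):
        det = DetectorConfig(pulse_tau=30e-9)
        stream = ArrivalStream(mode="events", span=(0, 1e-6),
                               times=np.array([100e-9, 110e-9]))
        out = apply_deadtime(stream, det)
        np.testing.assert_array_equal(out.times, [100e-9])

    def test_unsorted_input_rejected(self):
        det = DetectorConfig()
        stream = ArrivalStream(mode="events", span=(0, 1),
                               times=np.array([0.5, 0.1]))
        with pytest.raises(ValueError, match="sorted"):
            apply_deadtime(stream, det)

    def test_paralyzable_matches_closed_form(self, const_profile):
        """2 MHz homogeneous arrivals count at 2e6 * exp(-0.06) Hz."""
        det = DetectorConfig(dcr=0.0, deadtime_model="paralyzable")
        prof = const_profile(2e6, 1.0, 1e-3)
        stream = sample_arrivals(prof, det, mode="events", rng=substream(8, "p"))
        out = apply_deadtime(stream, det)
        counted = out.n_events / 1.0
        expected = expected_counted_rate(2e6, det)
        assert expected == pytest.approx(2e6 * np.exp(-0.06), rel=1e-12)
        assert abs(counted - expected) < 3 * np.sqrt(out.n_events)

    def test_nonparalyzable_matches_closed_form(self, const_profile):
        det = DetectorConfig(dcr=0.0, deadtime_model="nonparalyzable")
        prof = const_profile(1e6, 0.3, 1e-3)
        stream = sample_arrivals(prof, det, mode="events", rng=substream(9, "np"))
        out = apply_deadtime(stream, det)
        counted = out.n_events / 0.3
        expected = expected_counted_rate(1e6, det)
        assert expected == pytest.approx(1e6 / (1 + 1e6 * 30e-9), rel=1e-12)
        assert abs(counted - expected) < 3 * np.sqrt(out.n_events) / 0.3

    def test_binned_thinning_matches_closed_form(self, const_profile):
        det = DetectorConfig(dcr=0.0)
        prof = const_profile(2e6, 1.0, 1e-3)
        stream = sample_arrivals(prof, det, mode="binned", rng=substream(10, "b"))
        out = apply_deadtime(stream, det, rng=substream(10, "b2"))
        counted = out.counts.sum()
        expected = expected_counted_rate(2e6, det) * 1.0
        assert abs(counted - expected) < 3 * np.sqrt(expected)


class TestClosedForms:
    def test_expected_counted_rate_values(self, det):
        assert expected_counted_rate(0.0, det) == 0.0
        assert expected_counted_rate(2e6, det) == pytest.approx(1.8835e6, rel=1e-4)

    def test_paralyzable_maximum_at_inverse_tau(self, det):
        n_star = 1.0 / det.pulse_tau
        r_star = expected_counted_rate(n_star, det)
        assert r_star > expected_counted_rate(0.9 * n_star, det)
        assert r_star > expected_counted_rate(1.1 * n_star, det)

    def test_pileup_probability_values(self, det):
        assert pileup_probability(0.0, det) == 0.0
        assert pileup_probability(2e6, det) == pytest.approx(0.0582, abs=5e-4)
        assert pileup_probability(3.5e6, det) == pytest.approx(0.0997, abs=5e-4)

    @pytest.mark.parametrize("model", ["paralyzable", "nonparalyzable"])
    def test_loss_monotonicity(self, model):
        det = DetectorConfig(deadtime_model=model)
        rates = np.linspace(1e4, 2e7, 200)
        ratio = expected_counted_rate(rates, det) / rates
        assert np.all(np.diff(ratio) <= 1e-15)


class TestCountWindows:
    def test_ten_events_single_window(self):
        stream = ArrivalStream(mode="events", span=(0.0, 0.1),
                               times=np.linspace(0.0, 0.099, 10))
        trace = count_windows(stream, 0.1)
        assert len(trace.counts) == 1
        assert trace.freq[0] == pytest.approx(100.0)

    def test_empty_stream_zero_trace(self):
        stream = ArrivalStream(mode="events", span=(0.0, 1.0), times=np.array([]))
        trace = count_windows(stream, 0.1)
        assert len(trace.counts) == 10
        assert np.all(trace.counts == 0)

    def test_dark_window_statistics(self):
        """100 windows at 904 kHz: mean within 3 sigma/sqrt(100)."""
        det = DetectorConfig(dcr=904e3)
        prof = EmissionProfile.zero(10.0, 1e-3)
        stream = sample_arrivals(prof, det, mode="binned", rng=substream(11, "w"))
        trace = count_windows(stream, 0.1)
        sigma = np.sqrt(904e3 * 0.1) / 0.1
        assert len(trace.counts) == 100
        assert abs(trace.freq.mean() - 904e3) < 3 * sigma / 10

    def test_frequency_count_consistency(self):
        stream = ArrivalStream(mode="events", span=(0.0, 1.0),
                               times=np.sort(np.random.default_rng(3).random(500)))
        trace = count_windows(stream, 0.1)
        np.testing.assert_array_equal(trace.freq * trace.window, trace.counts)

    def test_scaler_saturation_flag_and_clip(self):
        edges = np.array([0.0, 0.1])
        stream = ArrivalStream(mode="binned", span=(0.0, 0.1), bin_edges=edges,
                               counts=np.array([70000]),
                               bin_rate=np.array([7e5]))
        trace = count_windows(stream, 0.1)
        assert trace.saturated[0] and trace.counts[0] == 70000
        clipped = count_windows(stream, 0.1, clip=True)
        assert clipped.counts[0] == 2 ** 16 - 1

    def test_round_trip(self, tmp_path):
        stream = ArrivalStream(mode="events", span=(0.0, 1.0),
                               times=np.sort(np.random.default_rng(4).random(200)))
        trace = count_windows(stream, 0.1)
        path = tmp_path / "trace.csv"
        write_count_trace(trace, path)
        back = read_count_trace(path)
        np.testing.assert_array_equal(back.counts, trace.counts)
        assert back.window == pytest.approx(trace.window)
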