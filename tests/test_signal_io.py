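"""Trace I/O, event detection, heatmap and event serialization."""

import numpy as np
import pytest

from subnanospec.encode import AB42, Peptide
from subnanospec.signal_io import (
    BlockadeEvent,
    RawTrace,
    blockade_heatmap,
    detect_events,
    read_events,
    read_trace,
    write_events,
    write_trace,
)
from subnanospec.simulate import SimulationConfig, simulate_trace


@pytest.fixture(scope="module")
def sim_config():
    # shorter, tighter duration distribution so events stay well inside the
    # running-median baseline window
    return SimulationConfig(
        peptide=Peptide(AB42, "AB42"),
        n_spectra=12,
        duration_sigma=0.5,
        seed=100,
    )


class TestReadTrace:
    def test_tsv_rate_from_spacing(self, tmp_path):
        p = tmp_path / "trace.tsv"
        p.write_text("time_s\tcurrent_pA\n0.0\t100\n0.000002\t101\n0.000004\t99\n")
        trace = read_trace(p)
        assert len(trace.samples) == 3
        assert trace.sampling_rate == pytest.approx(500_000.0)

    def test_empty_tsv_body_is_an_error(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("time_s\tcurrent_pA\n")
        with pytest.raises(ValueError, match="no samples"):
            read_trace(p)

    def test_bad_header_is_an_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("t\ti\n0\t1\n1\t2\n")
        with pytest.raises(ValueError, match="expected header"):
            read_trace(p)

    def test_unknown_format_tag(self, tmp_path):
        p = tmp_path / "trace.tsv"
        p.write_text("time_s\tcurrent_pA\n0\t1\n0.1\t2\n")
        with pytest.raises(ValueError, match="unknown trace format"):
            read_trace(p, format="hdf5")

    def test_abf_round_trip_is_sample_exact(self, tmp_path, rng):
        samples = rng.normal(200, 5, 4096).astype(np.float32).astype(float)
        trace = RawTrace(samples, 500_000.0)
        p = tmp_path / "trace.abf"
        write_trace(p, trace)
        back = read_trace(p)
        np.testing.assert_array_equal(back.samples, samples)
        assert back.sampling_rate == pytest.approx(500_000.0, rel=1e-6)

    def test_truncated_abf_names_the_problem(self, tmp_path):
        p = tmp_path / "short.abf"
        p.write_bytes(b"ABF " + b"\x00" * 100)
        with pytest.raises(ValueError, match="truncated ABF header"):
            read_trace(p, format="abf")

    def test_non_abf_signature_rejected(self, tmp_path):
        p = tmp_path / "junk.abf"
        p.write_bytes(b"JUNK" + b"\x00" * 3000)
        with pytest.raises(ValueError, match="bad signature at byte 0"):
            read_trace(p)


class TestDetectEvents:
    def test_flat_trace_has_no_events(self, rng):
        trace = RawTrace(np.full(10_000, 200.0) + rng.normal(0, 1, 10_000), 500_000.0)
        assert detect_events(trace) == []

    def test_constant_zero_trace_is_an_error(self):
        with pytest.raises(ValueError, match="no baseline"):
            detect_events(RawTrace(np.zeros(10_000), 500_000.0))

    def test_nonfinite_samples_rejected(self):
        s = np.full(10_000, 200.0)
        s[5] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            detect_events(RawTrace(s, 500_000.0))

    def test_single_rectangular_dip_recovered_exactly(self, rng):
        rate = 500_000.0
        s = 200.0 + rng.normal(0, 2, 20_000)
        s[8_000:8_100] -= 60.0  # 200 us dip, depth 30x noise SD
        events = detect_events(RawTrace(s, rate))
        assert len(events) == 1
        e = events[0]
        assert abs(e.start_time * rate - 8_000) <= 1
        assert abs(len(e.signal) - 100) <= 2
        assert e.signal.mean() == pytest.approx(60.0, abs=2.0)

    def test_two_separated_dips_in_time_order(self, rng):
        s = 200.0 + rng.normal(0, 2, 40_000)
        s[5_000:5_150] -= 50.0
        s[20_000:20_100] -= 50.0
        events = detect_events(RawTrace(s, 500_000.0))
        assert len(events) == 2
        assert events[0].start_time < events[1].start_time

    def test_blockade_identity_holds_samplewise(self, rng):
        s = 200.0 + rng.normal(0, 2, 20_000)
        s[9_000:9_080] -= 50.0
        (event,) = detect_events(RawTrace(s, 500_000.0))
        start = int(round(event.start_time * 500_000.0))
        raw = s[start : start + len(event.signal)]
        np.testing.assert_allclose(event.signal, event.open_current - raw, atol=0)

    def test_simulated_trace_events_recovered(self, sim_config):
        trace, truth = simulate_trace(sim_config)
        events = detect_events(trace, baseline_window=4001)
        starts = truth["start_sample"].to_numpy()
        recovered = 0
        for _, row in truth.iterrows():
            for e in events:
                s0 = e.start_time * trace.sampling_rate
                if abs(s0 - row.start_sample) <= 10:
                    recovered += 1
                    break
        assert recovered >= 0.95 * len(starts)


class TestBlockadeHeatmap:
    def _event(self, depth, n, i0=200.0):
        return BlockadeEvent(np.full(n, depth), 0.0, 500_000.0, i0)

    def test_mass_is_one_for_single_event(self):
        grid = blockade_heatmap([self._event(60.0, 100)])
        assert grid.shape == (150, 150)
        assert grid.sum() == pytest.approx(1.0, abs=1e-9)

    def test_duplicate_events_give_identical_grid(self):
        one = blockade_heatmap([self._event(60.0, 100)])
        two = blockade_heatmap([self._event(60.0, 100)] * 2)
        np.testing.assert_allclose(one, two, atol=1e-15)

    def test_unsmoothed_grid_matches_histogram_oracle(self, rng):
        events = [
            self._event(rng.uniform(10, 100), int(rng.integers(30, 300)))
            for _ in range(50)
        ]
        grid = blockade_heatmap(events, smooth_sigma=0.0)
        dt = np.array([e.duration_us for e in events])
        frac = np.array([e.fractional_blockade for e in events])
        expected, _, _ = np.histogram2d(
            dt, np.clip(frac, 0, 1), bins=(150, 150),
            range=((0, dt.max() * 1.05), (0, 1)),
        )
        np.testing.assert_allclose(grid, expected / expected.sum(), atol=1e-12)

    def test_zero_bins_rejected(self):
        with pytest.raises(ValueError, match="bin counts"):
            blockade_heatmap([self._event(60.0, 100)], bins=(0, 150))


class TestEventSerialization:
    def test_small_event_row_count(self, tmp_path):
        e = BlockadeEvent(np.arange(5.0) + 1, 0.01, 500_000.0, 200.0)
        p = tmp_path / "events.tsv"
        write_events(p, [e])
        lines = p.read_text().strip().split("\n")
        assert len(lines) == 7  # comment + header + 5 data rows

    def test_round_trip_on_random_events(self, tmp_path, rng):
        events = [
            BlockadeEvent(
                rng.normal(50, 5, int(rng.integers(20, 100))),
                float(rng.uniform(0, 10)),
                500_000.0,
                float(rng.uniform(150, 250)),
            )
            for _ in range(5)
        ]
        p = tmp_path / "events.tsv"
        write_events(p, events)
        back, rate = read_events(p)
        assert rate == 500_000.0
        assert len(back) == len(events)
        for a, b in zip(events, back):
            np.testing.assert_array_equal(a.signal, b.signal)
            assert a.start_time == b.start_time
            assert a.open_current == b.open_current

    def test_empty_list_round_trips(self, tmp_path):
        p = tmp_path / "empty.tsv"
        write_events(p, [], sampling_rate=500_000.0)
        events, rate = read_events(p)
        assert events == [] and rate == 500_000.0

    def test_mixed_sampling_rates_rejected(self, tmp_path):
        e1 = BlockadeEvent(np.ones(5), 0.0, 500_000.0, 200.0)
        e2 = BlockadeEvent(np.ones(5), 1.0, 250_000.0, 200.0)
        with pytest.raises(ValueError, match="mixed sampling rates"):
            write_events(tmp_path / "x.tsv", [e1, e2])
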