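"""Arrival-series construction and CSV exchange."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from molcomrx import (
    ArrivalSeries,
    Scenario,
    build_arrival_series,
    hitting_cdf,
    read_series_csv,
    split_molecules,
    write_series_csv,
)


class TestSplitMolecules:
    @pytest.mark.parametrize(
        "alpha, m, expected",
        [
            (0.15, 3_500_000, (2_975_000, 525_000)),  # the standard 85/15 split
            (0.0, 1000, (1000, 0)),
            (0.6, 3_500_000, (1_400_000, 2_100_000)),
        ],
    )
    def test_budget_split(self, alpha, m, expected):
        scenario = Scenario(alpha=alpha, total_molecules=m)
        a, b = split_molecules(scenario)
        assert (a, b) == pytest.approx(expected)

    @settings(max_examples=30, derandomize=True)
    @given(alpha=st.floats(0, 0.99), m=st.floats(0, 1e8))
    def test_split_sums_to_total(self, alpha, m):
        a, b = split_molecules(Scenario(alpha=alpha, total_molecules=m))
        assert a + b == pytest.approx(m, rel=1e-12, abs=1e-9)


class TestScenarioValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha": 1.0},
            {"alpha": -0.1},
            {"t_shift_s": -5.0},
            {"t_symbol_s": 0.0},
            {"bits": ""},
            {"bits": "0012"},
        ],
    )
    def test_invalid_scenarios_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Scenario(**kwargs)


class TestBuildArrivalSeries:
    def test_all_zero_bits_give_empty_signal(self, channel_a, channel_b):
        sc = Scenario(bits="0000000", t_symbol_s=200.0)
        series = build_arrival_series(sc, channel_a, channel_b)
        assert np.all(series.a_counts == 0)
        assert np.all(series.b_counts == 0)

    def test_single_bit_mass_conservation(self, channel_a, channel_b):
        # one bit-1, alpha=0: total arrivals approach M * (r/d) over a long horizon
        sc = Scenario(alpha=0.0, t_shift_s=0.0, bits="001", t_symbol_s=100.0, total_molecules=1e6)
        series = build_arrival_series(sc, channel_a, channel_b, horizon_s=5e6)
        limit = 1e6 * channel_a.capture_fraction
        assert series.a_counts.sum() == pytest.approx(limit, rel=1e-2)
        assert series.a_counts.sum() <= limit

    def test_superposition_of_two_symbols(self, channel_a, channel_b):
        base = dict(alpha=0.2, t_shift_s=80.0, t_symbol_s=400.0, sampling_interval_s=40.0)
        sc2 = Scenario(bits="0011", **base)
        horizon = sc2.duration_s + sc2.t_shift_s
        two = build_arrival_series(sc2, channel_a, channel_b, horizon_s=horizon)
        one_a = build_arrival_series(
            Scenario(bits="001", **base), channel_a, channel_b, horizon_s=horizon
        )
        one_b = build_arrival_series(
            Scenario(bits="0001", **base), channel_a, channel_b, horizon_s=horizon
        )
        np.testing.assert_allclose(two.a_counts, one_a.a_counts + one_b.a_counts, rtol=1e-12)
        np.testing.assert_allclose(two.b_counts, one_b.b_counts + one_a.b_counts, rtol=1e-12)

    def test_linearity_in_total_molecules(self, channel_a, channel_b):
        sc = Scenario(total_molecules=1e6, bits="00101", t_symbol_s=300.0)
        doubled = sc.with_(total_molecules=2e6)
        s1 = build_arrival_series(sc, channel_a, channel_b)
        s2 = build_arrival_series(doubled, channel_a, channel_b)
        np.testing.assert_allclose(s2.a_counts, 2 * s1.a_counts, rtol=1e-12)
        np.testing.assert_allclose(s2.b_counts, 2 * s1.b_counts, rtol=1e-12)

    def test_on_grid_shift_moves_b_by_one_sample(self, channel_a, channel_b):
        base = dict(bits="0010", t_symbol_s=400.0, sampling_interval_s=40.0, alpha=0.3)
        horizon = 4 * 400.0 + 400.0
        s0 = build_arrival_series(
            Scenario(t_shift_s=80.0, **base), channel_a, channel_b, horizon_s=horizon
        )
        s1 = build_arrival_series(
            Scenario(t_shift_s=120.0, **base), channel_a, channel_b, horizon_s=horizon
        )
        np.testing.assert_allclose(s1.b_counts[1:], s0.b_counts[:-1], rtol=1e-12)

    def test_horizon_must_cover_message(self, channel_a, channel_b):
        sc = Scenario(bits="0010", t_symbol_s=500.0, t_shift_s=100.0)
        with pytest.raises(ValueError, match="horizon"):
            build_arrival_series(sc, channel_a, channel_b, horizon_s=1999.0)

    def test_mismatched_geometry_rejected(self, channel_a):
        other = type(channel_a)(distance_um=100.0)
        with pytest.raises(ValueError, match="geometry"):
            build_arrival_series(Scenario(), channel_a, other)

    def test_mass_bound_multiple_symbols(self, channel_a, channel_b):
        sc = Scenario(alpha=0.15, bits="0010111100101", t_symbol_s=1500.0)
        series = build_arrival_series(sc, channel_a, channel_b)
        n_ones = sc.bits.count("1")
        bound_a = n_ones * 0.85 * sc.total_molecules * channel_a.capture_fraction
        bound_b = n_ones * 0.15 * sc.total_molecules * channel_b.capture_fraction
        assert series.a_counts.sum() <= bound_a
        assert series.b_counts.sum() <= bound_b


class TestCsvRoundTrip:
    def test_round_trip_is_lossless(self, channel_a, channel_b, tmp_path):
        sc = Scenario(alpha=0.15, t_shift_s=600.0, bits="0010111100101", t_symbol_s=1500.0)
        series = build_arrival_series(sc, channel_a, channel_b)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_series_csv(series, pa, pb)
        back = read_series_csv(pa, pb)
        np.testing.assert_array_equal(back.times_s, series.times_s)
        np.testing.assert_array_equal(back.a_counts, series.a_counts)
        np.testing.assert_array_equal(back.b_counts, series.b_counts)

    def test_empty_series_writes_header_only(self, tmp_path):
        empty = ArrivalSeries(np.array([]), np.array([]), np.array([]), sampling_interval_s=40.0)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_series_csv(empty, pa, pb)
        assert pa.read_text().strip() == "time_s,expected_count"
        back = read_series_csv(pa, pb)
        assert len(back) == 0

    def test_malformed_csv_reports_line(self, tmp_path):
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        pa.write_text("time_s,expected_count\n40.0,1.5\n80.0,oops\n")
        pb.write_text("time_s,expected_count\n40.0,0.5\n80.0,0.7\n")
        with pytest.raises(ValueError, match="line 3"):
            read_series_csv(pa, pb)

    def test_wrong_columns_rejected(self, tmp_path):
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        pa.write_text("t,n\n1,2\n")
        pb.write_text("t,n\n1,2\n")
        with pytest.raises(ValueError, match="columns"):
            read_series_csv(pa, pb)
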