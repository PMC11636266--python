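"""Receiver-circuit ODE model: structure, dynamics, events, invariants."""

import numpy as np
import pytest

from molcomrx import (
    SPECIES,
    ArrivalSeries,
    CircuitParams,
    Scenario,
    build_arrival_series,
    build_model,
    inject_arrivals,
    simulate,
)
from molcomrx.pipeline import simulate_message


def series_of(times, a, b):
    times = np.asarray(times, float)
    dt = times[1] - times[0] if len(times) > 1 else 40.0
    return ArrivalSeries(times, np.asarray(a, float), np.asarray(b, float), sampling_interval_s=dt)


class TestStructure:
    def test_species_and_reaction_counts(self, base_model):
        assert len(base_model.species) == 9
        assert len(base_model.reactions) == 17
        assert set(base_model.assignments) == {"LacI_free", "TetR_free"}

    def test_kseq_zero_decouples_arms(self, default_params, channel_a, channel_b):
        # with no sequestration, the Ai arm cannot see the B_e input
        params = default_params.with_(sequestration_rate=0.0)
        model = build_model(params)
        sc_b_only = Scenario(alpha=0.9, t_shift_s=0.0, bits="0010", t_symbol_s=400.0)
        series = build_arrival_series(sc_b_only, channel_a, channel_b)
        only_b = series_of(series.times_s, np.zeros(len(series)), series.b_counts)
        none = series_of(series.times_s, np.zeros(len(series)), np.zeros(len(series)))
        # tight integrator tolerances: remaining differences are pure round-off
        t_b = simulate(inject_arrivals(model, only_b), 1600.0, 40.0, rtol=1e-10, atol=1e-10)
        t_0 = simulate(inject_arrivals(model, none), 1600.0, 40.0, rtol=1e-10, atol=1e-10)
        np.testing.assert_allclose(t_b["Ai"], t_0["Ai"], rtol=1e-6, atol=1e-9)
        assert t_b["Bi"].max() > 10 * t_0["Bi"].max()

    def test_zero_synthesis_decays_to_zero(self):
        params = CircuitParams(
            transcription_rate_ai=0.0,
            transcription_rate_bi=0.0,
            repressor_synthesis_laci=0.0,
            repressor_synthesis_tetr=0.0,
        )
        init = np.full(len(SPECIES), 50.0)
        traj = simulate(build_model(params, initial_state=init), 20000.0, 500.0)
        assert traj.values.iloc[-1].max() < 1e-3

    def test_occupancy_promoter_variant_builds_and_runs(self, default_params):
        params = default_params.with_(promoter_model="occupancy")
        traj = simulate(build_model(params), 2000.0, 100.0)
        assert np.all(np.isfinite(traj.values.to_numpy()))


class TestInjection:
    def test_empty_series_leaves_model_unchanged(self, base_model):
        empty = series_of(np.array([40.0]), [0.0], [0.0])
        assert inject_arrivals(base_model, empty).events == base_model.events

    def test_single_event_jumps_iptg_exactly(self, base_model):
        series = series_of(np.array([200.0]), [1234.0], [0.0])
        model = inject_arrivals(base_model, series)
        traj = simulate(model, 400.0, 40.0)
        i = np.searchsorted(traj.times_s, 200.0)
        before, at = traj["IPTG"][i - 1], traj["IPTG"][i]
        # decay over the preceding 40 s is small; the jump dominates
        assert at - before == pytest.approx(1234.0, rel=5e-2)
        assert at >= 1234.0 * 0.99

    def test_total_injected_matches_series(self, base_model, channel_a, channel_b):
        sc = Scenario(bits="00101", t_symbol_s=300.0)
        series = build_arrival_series(sc, channel_a, channel_b)
        model = inject_arrivals(base_model, series)
        assert model.total_injected("IPTG") == pytest.approx(series.a_counts.sum(), rel=1e-12)
        assert model.total_injected("aTc") == pytest.approx(series.b_counts.sum(), rel=1e-12)

    def test_negative_counts_rejected(self, base_model):
        bad = ArrivalSeries.__new__(ArrivalSeries)  # bypass its own validation
        object.__setattr__(bad, "times_s", np.array([40.0]))
        object.__setattr__(bad, "a_counts", np.array([-1.0]))
        object.__setattr__(bad, "b_counts", np.array([0.0]))
        object.__setattr__(bad, "sampling_interval_s", 40.0)
        with pytest.raises(ValueError, match="nonnegative"):
            inject_arrivals(base_model, bad)


class TestDynamics:
    def test_native_state_reaches_positive_basal(self, base_model):
        # leaky basal expression: native Ai, Bi strictly positive constants
        traj = simulate(base_model, 21000.0, 40.0)
        end = traj.values.iloc[-1]
        assert end["Ai"] > 0 and end["Bi"] > 0
        late = traj.times_s > 18000.0
        assert np.ptp(traj["Ai"][late]) / end["Ai"] < 1e-3

    def test_tolerance_halving_changes_little(self, run_config, base_model):
        sc, series, _ = simulate_message(
            run_config, 0.15, 800.0, 1500.0, bits="0010000000000", base_model=base_model
        )
        model = inject_arrivals(base_model, series)
        horizon = sc.duration_s + sc.t_shift_s
        t1 = simulate(model, horizon, 40.0, rtol=1e-6, atol=1e-6)
        t2 = simulate(model, horizon, 40.0, rtol=5e-7, atol=5e-7)
        rel = np.abs(t1["Ai"] - t2["Ai"]).max() / np.abs(t1["Ai"]).max()
        assert rel < 1e-3

    def test_one_shot_rises_then_returns(self, run_config, native_state, base_model):
        _, _, traj = simulate_message(
            run_config, 0.15, 800.0, 1500.0, bits="0010000000000", base_model=base_model
        )
        ai = traj["Ai"]
        peak_idx = ai.argmax()
        assert ai[peak_idx] > 50 * native_state.basal_ai  # clear pulse
        assert traj.times_s[peak_idx] > 3000.0  # after the warm-up
        assert ai[-1] < 3 * native_state.basal_ai  # back toward basal

    def test_nonnegative_everywhere(self, run_config, base_model):
        _, _, traj = simulate_message(
            run_config, 0.5, 100.0, 1500.0, bits="0010000000000", base_model=base_model
        )
        assert traj.values.to_numpy().min() >= 0.0

    def test_integration_failure_reports_time(self, base_model):
        with pytest.raises(ValueError):
            simulate(base_model, -10.0, 40.0)


class TestPreEqualization:
    def test_residual_decreases_with_alpha(self, run_config, base_model):
        # the antagonist titrates the post-pulse tail: integrated Ai after the
        # peak shrinks (weakly) as more of the budget goes to B_e
        residuals = []
        for alpha in (0.0, 0.2, 0.4, 0.6):
            _, _, traj = simulate_message(
                run_config, alpha, 400.0, 1500.0, bits="0010000000000", base_model=base_model
            )
            ai = traj["Ai"]
            peak = ai.argmax()
            residuals.append(np.trapezoid(ai[peak:], traj.times_s[peak:]))
        assert all(r2 <= r1 * 1.001 for r1, r2 in zip(residuals, residuals[1:])), residuals

    def test_sequestration_off_makes_ai_alpha_insensitive(
        self, default_params, channel_a, channel_b
    ):
        # with k_seq=0 the B arm must not touch Ai even though alpha changes
        # the A_e budget is held fixed by scaling M to keep (1-alpha)M constant
        params = default_params.with_(sequestration_rate=0.0)
        model = build_model(params)
        trajs = []
        for alpha, m in ((0.0, 1e6), (0.5, 2e6)):
            sc = Scenario(alpha=alpha, t_shift_s=200.0, bits="0010", t_symbol_s=400.0, total_molecules=m)
            series = build_arrival_series(sc, channel_a, channel_b)
            trajs.append(
                simulate(inject_arrivals(model, series), 1800.0, 40.0, rtol=1e-10, atol=1e-10)
            )
        np.testing.assert_allclose(trajs[0]["Ai"], trajs[1]["Ai"], rtol=1e-6)
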