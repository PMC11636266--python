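"""End-to-end orchestration of the design-space exploration workflow.

The full run mirrors the period-finder procedure: establish the receiver's
native state, scan the (alpha, t_shift) grid with one-shot probes to infer
and filter symbol durations, simulate the intended message for every
retained scenario, score the scenarios with the MOL-eye metric, rank them,
and decode the message with the lambda threshold rule.  All tabular outputs
are CSV (the source of truth; plots are regenerated from them) and embed the
configuration hash.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .channel import WalkerConfig, compare_walkers_to_cdf, simulate_walkers
from .circuit import CircuitModel, Trajectory, build_model, inject_arrivals, simulate
from .config import RunConfig
from .moleye import DecisionResult, MolEyeResult, detect_bits, midpoint_lambda, moleye_score, rank_scenarios
from .period_finder import (
    NativeState,
    PeriodResult,
    find_native_state,
    heatmap_frame,
    scan_design_space,
)
from .signals import ArrivalSeries, Scenario, build_arrival_series, write_series_csv

__all__ = [
    "ScenarioEvaluation",
    "PipelineResult",
    "simulate_message",
    "evaluate_scenario",
    "run_pipeline",
    "validate_channel",
]

log = logging.getLogger("molcomrx")


@dataclass(frozen=True)
class ScenarioEvaluation:
    """Full-message evaluation of one retained scenario."""

    scenario: Scenario
    period: PeriodResult
    lambda_threshold: float
    moleye: MolEyeResult
    decision: DecisionResult


@dataclass(frozen=True)
class PipelineResult:
    native: NativeState
    scan: list
    evaluations: list  # ranked best-first
    out_dir: Path | None = None

    @property
    def retained(self) -> list:
        return [r for r in self.scan if r.retained]


def simulate_message(
    config: RunConfig,
    alpha: float,
    t_shift_s: float,
    t_symbol_s: float,
    bits: str | None = None,
    base_model: CircuitModel | None = None,
) -> tuple[Scenario, ArrivalSeries, Trajectory]:
    """Build the arrival series for a message and simulate the receiver."""
    scenario = Scenario(
        alpha=alpha,
        t_shift_s=t_shift_s,
        t_symbol_s=t_symbol_s,
        total_molecules=config.total_molecules,
        bits=config.bits if bits is None else bits,
        sampling_interval_s=config.sampling_interval_s,
    )
    series = build_arrival_series(scenario, config.channel_a, config.channel_b)
    model = base_model if base_model is not None else build_model(config.circuit)
    traj = simulate(
        inject_arrivals(model, series),
        scenario.duration_s + scenario.t_shift_s,
        config.sampling_interval_s,
    )
    return scenario, series, traj


def resolve_lambda(config: RunConfig, native: NativeState, period: PeriodResult) -> float:
    if config.lambda_policy == "midpoint":
        return midpoint_lambda(native.basal_ai, period.one_shot_peak_ai)
    return float(config.lambda_policy)


def evaluate_scenario(
    config: RunConfig,
    period: PeriodResult,
    native: NativeState,
    base_model: CircuitModel | None = None,
) -> ScenarioEvaluation:
    """Simulate the intended message at the inferred t_s and score/decode it."""
    if period.t_s_opt_s is None:
        raise ValueError("cannot evaluate a scenario without an inferred t_s")
    scenario, _series, traj = simulate_message(
        config, period.alpha, period.t_shift_s, period.t_s_opt_s, base_model=base_model
    )
    lam = resolve_lambda(config, native, period)
    eye = moleye_score(traj, scenario, period.t_s_opt_s, config.points_per_symbol)
    decision = detect_bits(traj, scenario, lam, statistic=config.detection_statistic)
    return ScenarioEvaluation(
        scenario=scenario, period=period, lambda_threshold=lam, moleye=eye, decision=decision
    )


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {cfg_hash}\n")
        df.to_csv(fh, index=index)


def run_pipeline(config: RunConfig, out_dir, plots: bool = True) -> PipelineResult:
    """Execute the full workflow and write all artifacts into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    config.to_yaml(out / "config.yaml")

    t0 = time.perf_counter()
    native = find_native_state(config.circuit)
    log.info("native state: Ai=%.3f Bi=%.3f rho0=%.4f", native.basal_ai, native.basal_bi, native.ratio)
    (out / "native_state.json").write_text(
        json.dumps(
            {
                "config_hash": cfg_hash,
                "basal_ai": native.basal_ai,
                "basal_bi": native.basal_bi,
                "ratio": native.ratio,
            },
            indent=2,
        )
    )

    timings = []

    def progress(res):
        timings.append(time.perf_counter())
        log.info(
            "scenario alpha=%.2f t_shift=%.0f: %s",
            res.alpha,
            res.t_shift_s,
            f"t_s_opt={res.t_s_opt_s:.0f} s retained={res.retained}"
            if res.t_s_opt_s is not None
            else res.reason,
        )

    base_model = build_model(config.circuit)
    scan = scan_design_space(
        config.circuit,
        config.channel_a,
        config.channel_b,
        config.alpha_grid,
        config.t_shift_grid,
        total_molecules=config.total_molecules,
        t_s_default=config.t_s_default,
        t_s_max=config.t_s_max,
        ratio_tolerance=config.ratio_tolerance,
        sampling_interval_s=config.sampling_interval_s,
        native=native,
        one_shot_bits=config.one_shot_bits,
        progress=progress,
    )
    stamps = np.array([t0] + timings)
    scan_log = pd.DataFrame(
        {
            "alpha": [r.alpha for r in scan],
            "t_shift_s": [r.t_shift_s for r in scan],
            "t_s_opt_s": [r.t_s_opt_s for r in scan],
            "retained": [r.retained for r in scan],
            "reason": [r.reason for r in scan],
            "wall_time_s": np.diff(stamps)[: len(scan)],
        }
    )
    _write_csv(scan_log, out / "scan_log.csv", cfg_hash)
    heat = heatmap_frame(scan)
    _write_csv(heat, out / "heatmap_t_s_opt.csv", cfg_hash, index=True)
    _write_csv(heat.attrs["retained"], out / "heatmap_retained.csv", cfg_hash, index=True)

    evaluations = []
    for period in (r for r in scan if r.retained):
        ev = evaluate_scenario(config, period, native, base_model)
        evaluations.append((ev.scenario, ev.moleye, ev))
        # persist the arrival series of the evaluated scenario
        _, series, _ = simulate_message(
            config, period.alpha, period.t_shift_s, period.t_s_opt_s, base_model=base_model
        )
        tag = f"a{period.alpha:.2f}_ts{period.t_shift_s:.0f}".replace(".", "p")
        write_series_csv(series, out / f"arrivals_Ae_{tag}.csv", out / f"arrivals_Be_{tag}.csv")

    ranked = rank_scenarios([(s, m) for s, m, _ in evaluations])
    by_key = {(s.alpha, s.t_shift_s): ev for s, _, ev in evaluations}
    ranked_evs = [by_key[(s.alpha, s.t_shift_s)] for s, _ in ranked]

    score_rows = pd.DataFrame(
        {
            "rank": np.arange(1, len(ranked_evs) + 1),
            "alpha": [ev.scenario.alpha for ev in ranked_evs],
            "t_shift_s": [ev.scenario.t_shift_s for ev in ranked_evs],
            "t_s_opt_s": [ev.period.t_s_opt_s for ev in ranked_evs],
            "score": [ev.moleye.score for ev in ranked_evs],
            "lambda_threshold": [ev.lambda_threshold for ev in ranked_evs],
            "decoded_bits": [ev.decision.decoded_bits for ev in ranked_evs],
            "bit_errors": [ev.decision.n_errors for ev in ranked_evs],
        }
    )
    _write_csv(score_rows, out / "scenario_scores.csv", cfg_hash)

    if plots and ranked_evs:
        from . import plots as _plots

        _plots.plot_heatmap(heat, out / "heatmap_t_s_opt.png")
        _plots.plot_eye(ranked_evs[0].moleye, out / "moleye_best.png")

    log.info(
        "pipeline done: %d scanned, %d retained, best score %s",
        len(scan),
        len(ranked_evs),
        f"{ranked_evs[0].moleye.score:.3g}" if ranked_evs else "n/a",
    )
    return PipelineResult(native=native, scan=scan, evaluations=ranked_evs, out_dir=out)


def validate_channel(
    config: RunConfig, horizon_s: float = 2000.0, n_quantiles: int = 9
) -> pd.DataFrame:
    """Monte-Carlo vs analytic agreement report for the A-molecule channel.

    Runs the Brownian walker oracle with the configured walker settings and
    compares its empirical absorption CDF against the closed form at the
    deciles of the observed hitting times.
    """
    result = simulate_walkers(config.channel_a, config.walker, horizon_s)
    return compare_walkers_to_cdf(config.channel_a, result, n_quantiles)
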