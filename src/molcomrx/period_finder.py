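"""Symbol-duration optimization over the (alpha, t_shift) design grid.

For each candidate pre-equalizer setting the receiver is probed with a
*one-shot* message — a single bit-1 preceded by the two-symbol warm-up and
followed by silence — at a deliberately long default symbol duration.  The
optimum symbol duration ``t_s_opt`` is the time the circuit needs to return
to its native equilibrium after that lone symbol: once the Bi/Ai ratio is
back within tolerance of the native ratio, the channel is considered clear
and the next symbol can be sent without interference.

Scenarios whose ``t_s_opt`` exceeds the maximum acceptable symbol duration
are discarded; the survivors go on to full-message simulation and MOL-eye
scoring.

Timing bookkeeping follows the toolbox convention of rescaling each
simulation onto a standard [0, 1000] axis before reading off spans, with
``dt = t_s_default * n_bits / 1000`` seconds per scaled unit; the rescaling
is an exact identity with the direct-seconds computation and both paths are
exposed for testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .channel import ChannelConfig
from .circuit import CircuitModel, CircuitParams, Trajectory, build_model, inject_arrivals, simulate
from .signals import ONE_SHOT_BITS, Scenario, build_arrival_series

__all__ = [
    "NativeState",
    "PeriodResult",
    "find_native_state",
    "infer_symbol_duration",
    "design_grid",
    "scan_design_space",
    "heatmap_frame",
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_T_SHIFT_GRID",
]

#: alpha in [0.15, 0.60] in steps of 0.05 — 10 values
DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.15, 0.601, 0.05), 2))
#: t_shift in [0, 1000] s in steps of 100 s — 11 values
DEFAULT_T_SHIFT_GRID = tuple(float(v) for v in range(0, 1001, 100))

WARMUP_SYMBOLS = 2


@dataclass(frozen=True)
class NativeState:
    """Basal expression levels of the unstimulated receiver."""

    basal_ai: float
    basal_bi: float

    def __post_init__(self) -> None:
        if not self.basal_ai > 0:
            raise ValueError("basal Ai must be > 0 for the Bi/Ai ratio to be finite")

    @property
    def ratio(self) -> float:
        """Native Bi/Ai ratio, the equilibrium reference of the period finder."""
        return self.basal_bi / self.basal_ai


@dataclass(frozen=True)
class PeriodResult:
    """Outcome of symbol-duration inference for one (alpha, t_shift) pair.

    ``t_a_s`` / ``t_b_s`` are the times of maximal Ai and maximal Bi/Ai on the
    one-shot response (seconds, post-warm-up); ``t_return_s`` the first output
    sample after both at which the ratio is back within tolerance of the
    native ratio.  ``t_s_opt_s`` is the span from the bit-1 slot start (the
    end of the warm-up) to ``t_return_s``.  ``retained`` requires a finite
    ``t_s_opt_s`` not exceeding ``t_s_max``.
    """

    alpha: float
    t_shift_s: float
    t_a_s: float
    t_b_s: float
    t_return_s: float | None
    t_s_opt_s: float | None
    retained: bool
    reason: str = ""
    degenerate: bool = False
    one_shot_peak_ai: float = float("nan")

    def __post_init__(self) -> None:
        if self.retained:
            if self.t_s_opt_s is None:
                raise ValueError("retained result must carry t_s_opt_s")
            if self.t_return_s is not None and not (
                self.t_return_s > self.t_a_s and self.t_return_s > self.t_b_s
            ):
                raise ValueError("t_return must lie after both t_A and t_B")


def find_native_state(
    params: CircuitParams,
    t_symbol_s: float = 3000.0,
    n_symbols: int = 7,
    output_step_s: float = 40.0,
    drift_tol: float = 1e-3,
) -> NativeState:
    """Simulate the receiver with no input (the all-zeros message) to equilibrium.

    The 0000000 message at a long symbol duration gives the circuit time to
    settle; convergence is accepted when the Bi/Ai ratio drifts by less than
    ``drift_tol`` (relative) over the trailing 10 % of the horizon.

    Raises
    ------
    RuntimeError
        If the ratio is still drifting at the end of the horizon.
    """
    model = build_model(params)
    horizon = n_symbols * t_symbol_s
    traj = simulate(model, horizon, output_step_s)
    rho = traj.ratio()
    tail = traj.times_s >= 0.9 * horizon
    drift = np.abs(rho[tail] - rho[-1]).max() / max(abs(rho[-1]), 1e-12)
    if drift > drift_tol:
        raise RuntimeError(
            f"native state not converged: trailing Bi/Ai drift {drift:.2e} > {drift_tol:.0e} "
            f"over horizon {horizon} s; extend the horizon or check parameters"
        )
    return NativeState(basal_ai=float(traj["Ai"][-1]), basal_bi=float(traj["Bi"][-1]))


def infer_symbol_duration(
    one_shot: Trajectory,
    native: NativeState,
    t_s_default: float,
    bits: str = ONE_SHOT_BITS,
    ratio_tolerance: float = 0.02,
    t_s_max: float = 2000.0,
    alpha: float = float("nan"),
    t_shift_s: float = float("nan"),
) -> PeriodResult:
    """Read the optimum symbol duration off a one-shot response.

    The trajectory time axis is rescaled to [0, 1000] (1000 scaled units over
    ``n_bits * t_s_default`` seconds).  On that axis the inference finds
    ``t_A`` (argmax of Ai) and ``t_B`` (argmax of Bi/Ai), both restricted to
    the post-warm-up region, then the first output sample ``t_R`` after both
    with ``|rho(t_R) - rho0| <= ratio_tolerance * rho0``.  No interpolation is
    applied: ``t_R`` is the first grid point satisfying the criterion.  The
    scaled span from the bit-1 slot start (warm-up end) to ``t_R`` times
    ``dt = t_s_default * n_bits / 1000`` is the optimum ``t_s`` in seconds.

    If the ratio never left the tolerance band after the warm-up the scenario
    is degenerate (nothing perturbed the receiver) and the minimal span is
    reported with ``degenerate=True``.
    """
    if bits[:WARMUP_SYMBOLS] != "0" * WARMUP_SYMBOLS:
        raise ValueError("one-shot bit strings must start with the 00 warm-up")
    n_bits = len(bits)
    dt_per_unit = t_s_default * n_bits / 1000.0  # seconds per scaled unit
    scaled_t = one_shot.times_s / dt_per_unit
    warmup_end_scaled = WARMUP_SYMBOLS * t_s_default / dt_per_unit

    rho = one_shot.ratio()
    rho0 = native.ratio
    post = scaled_t >= warmup_end_scaled
    if not post.any():
        raise ValueError("one-shot trajectory does not extend past the warm-up")

    ai = one_shot["Ai"]
    t_a = float(scaled_t[post][np.argmax(ai[post])])
    t_b = float(scaled_t[post][np.argmax(rho[post])])

    within = np.abs(rho - rho0) <= ratio_tolerance * abs(rho0)
    after = scaled_t > max(t_a, t_b)
    degenerate = bool(within[post].all())

    candidates = np.flatnonzero(after & within)
    common = dict(
        alpha=alpha,
        t_shift_s=t_shift_s,
        t_a_s=t_a * dt_per_unit,
        t_b_s=t_b * dt_per_unit,
        one_shot_peak_ai=float(ai[post].max()),
    )
    if len(candidates) == 0:
        return PeriodResult(
            t_return_s=None,
            t_s_opt_s=None,
            retained=False,
            reason=f"Bi/Ai never returned within {ratio_tolerance:.0%} of native over the horizon",
            degenerate=degenerate,
            **common,
        )
    t_r_scaled = float(scaled_t[candidates[0]])
    t_s_opt = (t_r_scaled - warmup_end_scaled) * dt_per_unit
    retained = t_s_opt <= t_s_max
    return PeriodResult(
        t_return_s=t_r_scaled * dt_per_unit,
        t_s_opt_s=t_s_opt,
        retained=retained,
        reason="" if retained else f"t_s_opt {t_s_opt:.0f} s exceeds t_s_max {t_s_max:.0f} s",
        degenerate=degenerate,
        **common,
    )


def design_grid(
    alpha_grid=DEFAULT_ALPHA_GRID, t_shift_grid=DEFAULT_T_SHIFT_GRID
) -> list[tuple[float, float]]:
    """All (alpha, t_shift) pairs of the design space, row-major in alpha."""
    if len(alpha_grid) == 0 or len(t_shift_grid) == 0:
        raise ValueError("design grids must be nonempty")
    return [(float(a), float(t)) for a in alpha_grid for t in t_shift_grid]


def scan_design_space(
    params: CircuitParams,
    channel_a: ChannelConfig,
    channel_b: ChannelConfig,
    alpha_grid=DEFAULT_ALPHA_GRID,
    t_shift_grid=DEFAULT_T_SHIFT_GRID,
    total_molecules: float = 3_500_000.0,
    t_s_default: float = 1500.0,
    t_s_max: float = 2000.0,
    ratio_tolerance: float = 0.02,
    sampling_interval_s: float = 40.0,
    native: NativeState | None = None,
    one_shot_bits: str = ONE_SHOT_BITS,
    progress=None,
) -> list[PeriodResult]:
    """Run one-shot inference for every pair of the design grids.

    A failure in one scenario (e.g. integrator breakdown) is recorded in that
    scenario's ``reason`` and the scan continues.  The result list covers the
    full grid in deterministic order.
    """
    pairs = design_grid(alpha_grid, t_shift_grid)
    if native is None:
        native = find_native_state(params)
    base = build_model(params)
    base.compiled()  # compile once; injection reuses the compiled RHS

    results: list[PeriodResult] = []
    for alpha, t_shift in pairs:
        try:
            scenario = Scenario(
                alpha=alpha,
                t_shift_s=t_shift,
                t_symbol_s=t_s_default,
                total_molecules=total_molecules,
                bits=one_shot_bits,
                sampling_interval_s=sampling_interval_s,
            )
            series = build_arrival_series(scenario, channel_a, channel_b)
            model = inject_arrivals(base, series)
            traj = simulate(model, scenario.duration_s + scenario.t_shift_s, sampling_interval_s)
            res = infer_symbol_duration(
                traj,
                native,
                t_s_default,
                bits=one_shot_bits,
                ratio_tolerance=ratio_tolerance,
                t_s_max=t_s_max,
                alpha=alpha,
                t_shift_s=t_shift,
            )
        except Exception as exc:  # record and continue: one bad cell must not kill the scan
            res = PeriodResult(
                alpha=alpha,
                t_shift_s=t_shift,
                t_a_s=float("nan"),
                t_b_s=float("nan"),
                t_return_s=None,
                t_s_opt_s=None,
                retained=False,
                reason=f"scenario failed: {exc}",
            )
        results.append(res)
        if progress is not None:
            progress(res)
    return results


def heatmap_frame(results: list[PeriodResult]) -> pd.DataFrame:
    """Pivot scan results into a heatmap table (rows alpha, columns t_shift).

    Cells hold ``t_s_opt_s``; scenarios with no equilibrium return are NaN.
    A parallel boolean mask of retained cells is available via
    ``heatmap_frame(results).attrs["retained"]``.
    """
    df = pd.DataFrame(
        {
            "alpha": [r.alpha for r in results],
            "t_shift_s": [r.t_shift_s for r in results],
            "t_s_opt_s": [r.t_s_opt_s if r.t_s_opt_s is not None else np.nan for r in results],
            "retained": [r.retained for r in results],
        }
    )
    heat = df.pivot(index="alpha", columns="t_shift_s", values="t_s_opt_s")
    heat.attrs["retained"] = df.pivot(index="alpha", columns="t_shift_s", values="retained")
    return heat
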