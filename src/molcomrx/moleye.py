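"""MOL-eye scoring, scenario ranking, and threshold detection.

The MOL-eye is the molecular-communication analogue of the eye diagram: the
post-warm-up Ai trace is cut into per-symbol segments, the segments are
superimposed on a common within-symbol grid, and the opening between the
*minimum* of all bit-1 segments and the *maximum* of all bit-0 segments is
accumulated pointwise (negative gaps count as zero).  The sum, multiplied by
the optimum symbol duration, is the scenario's score — larger is better.
Using the worst bit-1 against the worst bit-0 makes the score a pessimistic
(noise-robust) measure of how separable the two symbols are.

Detection itself is a threshold rule: a slot decodes as bit-1 when the Ai
readout reaches the concentration threshold lambda within the slot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit import Trajectory
from .period_finder import WARMUP_SYMBOLS
from .signals import Scenario

__all__ = [
    "MolEyeResult",
    "DecisionResult",
    "segment_traces",
    "moleye_score",
    "rank_scenarios",
    "detect_bits",
    "midpoint_lambda",
]


@dataclass(frozen=True)
class MolEyeResult:
    """Eye traces and score of one scenario.

    ``grid_scaled`` is the common within-symbol axis on the standard [0, 1000]
    rescaling of the full message (one symbol spans ``1000 / n_bits`` scaled
    units).  ``bit1_traces`` has one row per post-warm-up bit-1 symbol,
    ``bit0_traces`` per bit-0 symbol.
    """

    grid_scaled: np.ndarray
    bit1_traces: np.ndarray
    bit0_traces: np.ndarray
    lower_envelope: np.ndarray  # pointwise min over bit-1 traces
    upper_envelope: np.ndarray  # pointwise max over bit-0 traces
    score: float
    t_s_opt_s: float

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("MOL-eye score is a sum of nonnegative gaps; cannot be negative")

    @property
    def n_segments(self) -> int:
        return len(self.bit1_traces) + len(self.bit0_traces)


@dataclass(frozen=True)
class DecisionResult:
    """Threshold-detection outcome for one transmitted message."""

    lambda_threshold: float
    decoded_bits: str
    true_bits: str  # post-warm-up part of the transmitted message
    n_errors: int

    @property
    def error_positions(self) -> list[int]:
        """Post-warm-up symbol indices (0-based) decoded incorrectly."""
        return [i for i, (d, t) in enumerate(zip(self.decoded_bits, self.true_bits)) if d != t]


def segment_traces(
    traj: Trajectory, scenario: Scenario, t_symbol_s: float, points_per_symbol: int = 200
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cut the Ai trace into per-symbol segments on a common grid.

    Returns ``(grid_offsets_s, bit1_traces, bit0_traces)`` where the traces
    are linearly interpolated onto ``points_per_symbol`` offsets spanning one
    symbol.  The two warm-up symbols are excluded.
    """
    bits = scenario.bits
    offsets = np.linspace(0.0, t_symbol_s, points_per_symbol, endpoint=False)
    ai = traj["Ai"]
    t = traj.times_s
    ones, zeros = [], []
    for k in range(WARMUP_SYMBOLS, len(bits)):
        seg_t = k * t_symbol_s + offsets
        if seg_t[-1] > t[-1] + 1e-9:
            raise ValueError(
                f"trajectory (ends {t[-1]:.0f} s) does not cover symbol {k} "
                f"(needs {seg_t[-1]:.0f} s)"
            )
        seg = np.interp(seg_t, t, ai)
        (ones if bits[k] == "1" else zeros).append(seg)
    return offsets, np.array(ones), np.array(zeros)


def moleye_score(
    traj: Trajectory,
    scenario: Scenario,
    t_s_opt: float,
    points_per_symbol: int = 200,
) -> MolEyeResult:
    """Score a full-message simulation with the MOL-eye metric.

    The trajectory must have been simulated with ``scenario.bits`` at symbol
    duration ``t_s_opt``.  Score = ``t_s_opt * sum_j max(0, min_1(tau_j) -
    max_0(tau_j))`` over the common within-symbol grid.

    Raises
    ------
    ValueError
        If the post-warm-up message lacks bit-1 or bit-0 symbols — the eye
        needs both groups.
    """
    offsets, ones, zeros = segment_traces(traj, scenario, t_s_opt, points_per_symbol)
    if len(ones) == 0 or len(zeros) == 0:
        raise ValueError(
            "MOL-eye needs at least one bit-1 and one bit-0 symbol after the warm-up"
        )
    lower = ones.min(axis=0)
    upper = zeros.max(axis=0)
    opening = np.maximum(0.0, lower - upper)
    score = float(t_s_opt * opening.sum())
    # report the grid on the standard [0, 1000] axis of the full message
    dt_per_unit = t_s_opt * len(scenario.bits) / 1000.0
    return MolEyeResult(
        grid_scaled=offsets / dt_per_unit,
        bit1_traces=ones,
        bit0_traces=zeros,
        lower_envelope=lower,
        upper_envelope=upper,
        score=score,
        t_s_opt_s=t_s_opt,
    )


def rank_scenarios(results: list[tuple[Scenario, MolEyeResult]]) -> list[tuple[Scenario, MolEyeResult]]:
    """Scenarios ordered best-first: descending score, ties by (alpha, t_shift)."""
    return sorted(results, key=lambda pair: (-pair[1].score, pair[0].alpha, pair[0].t_shift_s))


def midpoint_lambda(basal_ai: float, one_shot_peak_ai: float) -> float:
    """Default detection threshold: midway between basal and one-shot peak Ai."""
    if one_shot_peak_ai < basal_ai:
        raise ValueError("one-shot peak below basal level; no usable threshold")
    return 0.5 * (basal_ai + one_shot_peak_ai)


def detect_bits(
    traj: Trajectory,
    scenario: Scenario,
    lambda_threshold: float,
    t_symbol_s: float | None = None,
    statistic: str = "max",
) -> DecisionResult:
    """Decode the post-warm-up symbols by thresholding the Ai readout.

    A slot decodes as bit-1 when its decision statistic reaches
    ``lambda_threshold``: with ``statistic="max"`` (default) the maximum Ai
    anywhere within the slot — any-time exceedance — and with
    ``statistic="end"`` the Ai value at the slot's last sample.
    """
    if not lambda_threshold > 0:
        raise ValueError("lambda_threshold must be > 0")
    if statistic not in ("max", "end"):
        raise ValueError(f"unknown decision statistic {statistic!r}")
    t_s = scenario.t_symbol_s if t_symbol_s is None else t_symbol_s
    t = traj.times_s
    ai = traj["Ai"]
    decoded = []
    for k in range(WARMUP_SYMBOLS, len(scenario.bits)):
        in_slot = (t >= k * t_s) & (t < (k + 1) * t_s)
        if not in_slot.any():
            raise ValueError(f"trajectory has no samples in symbol slot {k}")
        stat = ai[in_slot].max() if statistic == "max" else ai[in_slot][-1]
        decoded.append("1" if stat >= lambda_threshold else "0")
    decoded_str = "".join(decoded)
    true = scenario.bits[WARMUP_SYMBOLS:]
    n_err = sum(d != b for d, b in zip(decoded_str, true))
    return DecisionResult(
        lambda_threshold=float(lambda_threshold),
        decoded_bits=decoded_str,
        true_bits=true,
        n_errors=n_err,
    )
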