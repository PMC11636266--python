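"""Plots for design-space scans and MOL-eye diagrams (regenerable from CSVs)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_heatmap(heat: pd.DataFrame, path) -> None:
    """Heatmap of inferred t_s_opt over the (alpha, t_shift) grid.

    NaN cells (no equilibrium return within the horizon) are hatched grey.
    """
    fig, ax = plt.subplots(figsize=(8, 5))
    data = heat.to_numpy(dtype=float)
    masked = np.ma.masked_invalid(data)
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("lightgrey")
    im = ax.imshow(masked, aspect="auto", cmap=cmap, origin="lower")
    ax.set_xticks(range(len(heat.columns)), [f"{c:.0f}" for c in heat.columns])
    ax.set_yticks(range(len(heat.index)), [f"{i:.2f}" for i in heat.index])
    ax.set_xlabel("t_shift (s)")
    ax.set_ylabel("alpha (B_e fraction)")
    fig.colorbar(im, ax=ax, label="t_s_opt (s)")
    ax.set_title("Inferred optimum symbol duration")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_eye(eye, path) -> None:
    """Superimposed per-symbol Ai traces with the eye envelopes."""
    fig, ax = plt.subplots(figsize=(7, 5))
    for seg in eye.bit1_traces:
        ax.plot(eye.grid_scaled, seg, color="tab:blue", alpha=0.6, lw=1)
    for seg in eye.bit0_traces:
        ax.plot(eye.grid_scaled, seg, color="tab:red", alpha=0.6, lw=1)
    ax.plot(eye.grid_scaled, eye.lower_envelope, color="tab:blue", lw=2, label="min over bit-1")
    ax.plot(eye.grid_scaled, eye.upper_envelope, color="tab:red", lw=2, label="max over bit-0")
    ax.fill_between(
        eye.grid_scaled,
        eye.upper_envelope,
        np.maximum(eye.lower_envelope, eye.upper_envelope),
        color="gold",
        alpha=0.3,
        label="eye opening",
    )
    ax.set_xlabel("within-symbol time (scaled units)")
    ax.set_ylabel("free Ai (molecules/cell)")
    ax.set_title(f"MOL-eye diagram (score {eye.score:.3g})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
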