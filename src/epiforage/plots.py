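"""Optional figure helpers mirroring the standard diagnostic panels."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .responses import ResponseTraces, SweepResult


def plot_trial(traces: ResponseTraces, path: str) -> None:
    """Raster, average LFP (raw + band-limited) and dopamine for one trial."""
    fig, axes = plt.subplots(3, 1, figsize=(8, 9), constrained_layout=True)
    axes[0].imshow(1.0 - traces.raster, aspect="auto", cmap="gray", interpolation="nearest")
    axes[0].set_title("Unit firing (black = probability 1)")
    axes[0].set_xlabel("update bin")
    axes[0].set_ylabel("unit (epoch x state)")
    axes[1].plot(traces.time_axis, traces.lfp_avg, ":", color="gray", label="raw")
    axes[1].plot(traces.time_axis, traces.lfp_avg_filtered, "k", label="4 Hz band")
    axes[1].set_title("Average local field potential")
    axes[1].set_xlabel("time (s)")
    axes[1].legend(frameon=False)
    axes[2].bar(traces.time_axis, traces.dopamine, width=traces.time_axis[0] * 0.9, color="k")
    axes[2].set_title("Simulated dopamine (precision + rate of change)")
    axes[2].set_xlabel("time (s)")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_sweep(result: SweepResult, path: str) -> None:
    """Accuracy / decision-time / reaction-time heat maps over the grid."""
    fig, axes = plt.subplots(1, 3, figsize=(13, 4), constrained_layout=True)
    panels = [
        ("Accuracy (%)", result.accuracy),
        ("Decision time (saccades)", result.decision_time),
        ("Reaction time (iterations)", result.reaction_time),
    ]
    for ax, (title, grid) in zip(axes, panels):
        im = ax.imshow(grid, aspect="auto", origin="lower", cmap="viridis")
        ax.set_title(title)
        ax.set_xlabel("prior precision (1/beta, increasing)")
        ax.set_ylabel("preference strength c")
        ax.set_xticks(range(len(result.beta_levels)))
        ax.set_xticklabels([f"{1/b:.2g}" for b in result.beta_levels], rotation=45)
        ax.set_yticks(range(len(result.c_levels)))
        ax.set_yticklabels([f"{c:.2g}" for c in result.c_levels])
        fig.colorbar(im, ax=ax)
    fig.savefig(path, dpi=120)
    plt.close(fig)
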