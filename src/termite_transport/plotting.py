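"""Thin matplotlib helpers: E-maps, jam maps, PRCC bars, space-time plots."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_map(grid, xlabel: str, ylabel: str, title: str, out_path) -> None:
    """Heat map of a pivoted sweep grid (rows = first axis)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(
        np.asarray(grid, dtype=float),
        origin="lower",
        aspect="auto",
        extent=[
            grid.columns.min() - 0.5,
            grid.columns.max() + 0.5,
            grid.index.min() - 0.5,
            grid.index.max() + 0.5,
        ],
    )
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def plot_prcc_bars(prcc: dict, out_path) -> None:
    """Bar chart of PRCC per control variable."""
    names = list(prcc)
    vals = [prcc[n] for n in names]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(names, vals, color=["tab:red" if v < 0 else "tab:blue" for v in vals])
    ax.axhline(0, color="k", lw=0.8)
    ax.set_ylabel("PRCC")
    ax.set_ylim(-1, 1)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def plot_efficiency(mean_E: np.ndarray, out_path, label: str = "E(t)") -> None:
    """Replicate-averaged transport efficiency over time."""
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(np.arange(1, mean_E.size + 1), mean_E, lw=1.0, label=label)
    ax.set_xlabel("t")
    ax.set_ylabel("E")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def plot_space_time(trajectory, jam_log, out_path, max_steps: int = 2000) -> None:
    """Space-time scatter of agent positions; jammed agents highlighted."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for t, pos, dirn, state, _cargo in trajectory[:max_steps]:
        jammed = state == 2
        ax.scatter(pos[~jammed], np.full((~jammed).sum(), t), s=0.2, c="tab:blue")
        if jammed.any():
            ax.scatter(pos[jammed], np.full(jammed.sum(), t), s=0.6, c="tab:green")
    ax.set_xlabel("x (site)")
    ax.set_ylabel("t")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
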