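"""Optional plotting helpers (matplotlib imported lazily; never load-bearing)."""
from __future__ import annotations

import numpy as np


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_trajectory(trajectory, path=None, log_x=False):
    """Time series of tumor, T cell, and cytokine volumes."""
    plt = _plt()
    fig, axes = plt.subplots(3, 1, sharex=True, figsize=(7, 6))
    labels = ["tumor x (cm$^3$)", "CD4$^+$ T cells y (cm$^3$)", "cytokine z (cm$^3$)"]
    for i, (ax, label) in enumerate(zip(axes, labels)):
        ax.plot(trajectory.times, trajectory.states[:, i], lw=0.8)
        ax.set_ylabel(label)
        if i == 0 and log_x:
            ax.set_yscale("log")
    axes[-1].set_xlabel("t (days)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_sweep(records, path=None):
    """Tumor extrema of the attractor versus the swept parameter."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 4))
    values = [r.value for r in records]
    ax.plot(values, [r.x_min for r in records], ".", ms=3, label="min x")
    ax.plot(values, [r.x_max for r in records], ".", ms=3, label="max x")
    ax.set_xlabel("parameter")
    ax.set_ylabel("tumor volume extrema (cm$^3$)")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_region_map(region_map, path=None):
    """Leaf cells of a two-parameter region map, colored by label."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 5))
    labels = sorted({c[4] for c in region_map.cells})
    cmap = plt.get_cmap("tab10")
    colors = {lab: cmap(i % 10) for i, lab in enumerate(labels)}
    for x0, x1, y0, y1, lab in region_map.cells:
        ax.add_patch(
            plt.Rectangle((x0, y0), x1 - x0, y1 - y0, facecolor=colors[lab], edgecolor="none")
        )
    ax.set_xlim(*region_map.ranges[0])
    ax.set_ylim(*region_map.ranges[1])
    ax.set_xlabel(region_map.axes[0])
    ax.set_ylabel(region_map.axes[1])
    handles = [plt.Rectangle((0, 0), 1, 1, facecolor=colors[lab]) for lab in labels]
    ax.legend(handles, labels, fontsize=7, loc="upper right")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_surfaces(surfaces, path=None):
    """3D view of the Hopf surface b(m, beta) and the transcritical plane."""
    plt = _plt()
    from mpl_toolkits.mplot3d import Axes3D  # noqa: F401

    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d")
    M, B = np.meshgrid(surfaces["m"], surfaces["beta"], indexing="ij")
    ax.plot_surface(M, B, surfaces["hopf_b"], alpha=0.7, cmap="viridis")
    bc = surfaces["transcritical_beta"]
    mm = surfaces["m"]
    bb = np.linspace(np.nanmin(surfaces["hopf_b"]), np.nanmax(surfaces["hopf_b"]), 2)
    Mp, Bp = np.meshgrid(mm, bb, indexing="ij")
    ax.plot_surface(Mp, np.full_like(Mp, bc), Bp, alpha=0.3, color="red")
    ax.set_xlabel("m (cm$^3$)")
    ax.set_ylabel(r"$\beta$ (day$^{-1}$)")
    ax.set_zlabel("b (cm$^3$)")
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
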