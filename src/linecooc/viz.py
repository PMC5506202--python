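"""Plotting helpers for kernels and grouping results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .connectivity import xy_marginal

__all__ = ["plot_kernel_slices", "plot_xy_marginal", "plot_label_map"]


def plot_kernel_slices(kernel, layers=None, clip_frac: float = 0.2, path=None):
    """Montage of fixed-relative-orientation kernel layers.

    By default shows the five layers nearest relative angles
    {-pi/8, -pi/16, 0, pi/16, pi/8}; values are clipped at ``clip_frac`` of
    the maximum for visibility of the tails.
    """
    vals = kernel.values
    n = kernel.n_theta
    if layers is None:
        step = np.pi / n
        wanted = np.array([-np.pi / 8, -np.pi / 16, 0.0, np.pi / 16, np.pi / 8])
        layers = sorted({int(np.rint(w / step)) % n for w in wanted})
    vmax = clip_frac * vals.max()
    fig, axes = plt.subplots(1, len(layers), figsize=(3 * len(layers), 3))
    if len(layers) == 1:
        axes = [axes]
    for ax, j in zip(axes, layers):
        ax.imshow(vals[:, :, j].T, vmin=0, vmax=vmax, cmap="inferno", origin="upper")
        ax.set_title(f"rel. angle {j}·π/{n}")
        ax.axis("off")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_xy_marginal(kernel, path=None):
    """Spatial marginal (sum over orientations) of a kernel."""
    marg = xy_marginal(kernel)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(marg.T, cmap="inferno", origin="upper")
    ax.set_title("xy marginal")
    ax.axis("off")
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_label_map(image, label_map, path=None):
    """Overlay a grouping label map on the source image."""
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(image, cmap="gray")
    masked = np.ma.masked_where(label_map < 0, label_map)
    ax.imshow(masked, cmap="tab10", alpha=0.6, interpolation="nearest")
    ax.axis("off")
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
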