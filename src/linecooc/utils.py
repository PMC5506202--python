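"""Shared angle-bin and grid conventions.

All modules use one raster frame: ``x`` is the column index, ``y`` the row
index, and angles are measured from the +x axis toward the +y axis. Absolute
(line) orientations are pi-periodic and discretized on ``n_theta`` bins

    theta_k = -pi/2 + k * pi / n_theta,   k = 0 .. n_theta - 1,

while *relative* orientations (the theta axis of co-occurrence and
connectivity kernels) are stored so that layer ``j`` holds the relative angle
``j * pi / n_theta`` (layer 0 = aligned elements).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "theta_bins",
    "angle_to_bin",
    "fold_pi",
    "rotate_offsets",
]


def theta_bins(n_theta: int) -> np.ndarray:
    """Absolute orientation bin centers ``-pi/2 + k*pi/n_theta``."""
    if n_theta < 1:
        raise ValueError("n_theta must be >= 1")
    return -np.pi / 2 + np.arange(n_theta) * np.pi / n_theta


def fold_pi(angle):
    """Fold an angle (radians) to the pi-periodic range [-pi/2, pi/2)."""
    return np.mod(np.asarray(angle) + np.pi / 2, np.pi) - np.pi / 2


def angle_to_bin(angle, n_theta: int):
    """Nearest absolute orientation bin index for a (pi-periodic) angle."""
    step = np.pi / n_theta
    idx = np.rint((fold_pi(angle) + np.pi / 2) / step).astype(int)
    return np.mod(idx, n_theta)


def rotate_offsets(dx, dy, theta):
    """Rotate offset vectors by ``-theta`` (into the frame of a reference
    element whose orientation is ``theta``)."""
    c, s = np.cos(theta), np.sin(theta)
    return c * dx + s * dy, -s * dx + c * dy
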