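import numpy as np
import pytest

import linecooc as lc


@pytest.fixture(scope="session")
def small_stack():
    """16-orientation cake wavelets at a size fast enough for unit tests."""
    return lc.make_cake_wavelets(16, 51)


@pytest.fixture(scope="session")
def line_image():
    """Dark horizontal 1-px line on a bright background."""
    img = np.full((61, 61), 0.9)
    img[30, :] = 0.2
    return img


@pytest.fixture(scope="session")
def grouping_kernel():
    """Normalized symmetrized direction-process kernel for grouping tests."""
    gamma = lc.fp_resolvent_series(
        [0.02], 0.002, d=30, n_theta=16, renormalize=False, dt=0.75
    )[0]
    return lc.normalize_kernel(lc.symmetrize_projective(gamma).fold())


def brute_force_histogram(points, d, n_theta):
    """Independent O(N^2) pair-enumeration oracle for the co-occurrence
    kernel: plain Python loops, no shared code with the implementation."""
    side = 2 * d + 1
    hist = np.zeros((side, side, n_theta))
    bins = [-np.pi / 2 + k * np.pi / n_theta for k in range(n_theta)]
    n = len(points.x)
    for i in range(n):
        if points.theta is not None:
            th = float(points.theta[i])
        else:
            th = bins[int(points.k[i])]
        for j in range(n):
            if i == j:
                continue
            dx = float(points.x[j] - points.x[i])
            dy = float(points.y[j] - points.y[i])
            if abs(dx) > d or abs(dy) > d:
                continue
            c, s = np.cos(th), np.sin(th)
            rx = int(round(c * dx + s * dy))
            ry = int(round(-s * dx + c * dy))
            if abs(rx) > d or abs(ry) > d:
                continue
            if points.theta is not None:
                dth = float(points.theta[j]) - th
                dk = int(round((dth % np.pi) / (np.pi / n_theta))) % n_theta
            else:
                dk = (int(points.k[j]) - int(points.k[i])) % n_theta
            hist[rx + d, ry + d, dk] += 0.5
            hist[-rx + d, -ry + d, dk] += 0.5
    return hist


def agreement_score(label_map, truth, overlap):
    """Fraction of scored pixels whose predicted group maps bijectively onto
    the ground-truth curve with which it mostly overlaps."""
    mask = (truth > 0) & ~overlap
    pred = label_map[mask]
    true = truth[mask]
    agree = 0
    used = set()
    for g in np.unique(pred[pred >= 0]):
        sel = pred == g
        maj = int(np.bincount(true[sel]).argmax())
        if maj in used:  # two predicted groups mapping to one curve
            continue
        used.add(maj)
        agree += int((true[sel] == maj).sum())
    return agree / int(mask.sum())
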