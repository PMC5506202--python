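"""Shift-twist invariant line co-occurrence kernels.

From binary centerlines and a dominant-orientation map, every centerline pixel
becomes an interest point (x, y, k). For each ordered pair of nearby points
the spatial offset is rotated into the frame of the reference point and the
relative orientation is taken modulo pi, making the resulting difference set
invariant under joint translations and rotations (shift-twist transformations).
Because centerlines carry no polarity, each ordered pair also contributes the
antipodal representative (reference orientation + pi), at weight 1/2 each, so
the accumulated histogram is symmetric under spatial point reflection.

The histogram over a (2d+1) x (2d+1) x n_theta grid, l1-normalized, is the
data-driven ("statistical") kernel; layer j of the theta axis holds relative
orientation j*pi/n_theta (layer 0 = aligned pairs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.morphology import skeletonize
from sklearn.base import BaseEstimator

from .oscore import OrientationMap
from .utils import rotate_offsets, theta_bins

__all__ = [
    "CenterlineMask",
    "InterestPointSet",
    "ShiftTwistDifferenceSet",
    "CooccurrenceKernel",
    "thin_to_centerlines",
    "build_interest_points",
    "shift_twist_differences",
    "accumulate_kernel",
    "normalize_kernel",
    "combine_av_kernels",
    "kernel_distance",
    "LineCooccurrence",
]


@dataclass
class InterestPointSet:
    """Centerline pixels lifted to (x, y, orientation bin).

    ``theta`` optionally carries continuous (unbinned) orientations — e.g.
    true tangents of synthetic paths. When present it is used for the
    shift-twist rotation and for binning the relative orientation directly,
    which avoids the double-binning smear of bin-valued orientations; the
    image pipeline (binned dominant orientations) leaves it unset.
    """

    x: np.ndarray
    y: np.ndarray
    k: np.ndarray
    n_theta: int
    theta: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class ShiftTwistDifferenceSet:
    """Weighted multiset of rotated pair differences (dx, dy, dk)."""

    dx: np.ndarray
    dy: np.ndarray
    dk: np.ndarray
    weight: np.ndarray
    d: int
    n_theta: int

    def __len__(self) -> int:
        return len(self.dx)


@dataclass
class CooccurrenceKernel:
    """(2d+1) x (2d+1) x n_theta nonnegative histogram.

    Axis 0 is dx + d, axis 1 is dy + d, axis 2 the relative-orientation layer.
    """

    values: np.ndarray
    d: int
    n_theta: int
    normalized: bool = False

    @property
    def shape(self):
        return self.values.shape

    def copy(self) -> "CooccurrenceKernel":
        return CooccurrenceKernel(
            self.values.copy(), self.d, self.n_theta, self.normalized
        )


CenterlineMask = np.ndarray  # binary grid alias


def thin_to_centerlines(mask: np.ndarray) -> np.ndarray:
    """Morphological thinning to a 1-px-wide, connectivity-preserving skeleton."""
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1, False, True))):
        raise ValueError("thin_to_centerlines expects a binary mask")
    return skeletonize(mask.astype(bool)).astype(np.uint8)


def build_interest_points(
    centerlines: np.ndarray, orientations: OrientationMap
) -> InterestPointSet:
    """One interest point per centerline pixel with its dominant bin."""
    centerlines = np.asarray(centerlines).astype(bool)
    if centerlines.shape != orientations.angle_index.shape:
        raise ValueError("centerline and orientation shapes differ")
    undefined = centerlines & ~orientations.defined_mask
    if np.any(undefined):
        ys, xs = np.nonzero(undefined)
        raise ValueError(
            f"centerline pixel (x={xs[0]}, y={ys[0]}) has no defined orientation"
        )
    rows, cols = np.nonzero(centerlines)
    return InterestPointSet(
        x=cols.astype(int),
        y=rows.astype(int),
        k=orientations.angle_index[rows, cols].astype(int),
        n_theta=orientations.n_theta,
    )


def shift_twist_differences(points: InterestPointSet, d: int) -> ShiftTwistDifferenceSet:
    """Rotated differences of all ordered pairs within Chebyshev distance d.

    For an ordered pair (p, q) the offset is rotated by -theta_p and rounded
    to the nearest pixel; the relative orientation bin is (k_q - k_p) mod
    n_theta. The antipodal representative (theta_p + pi) contributes the point-
    reflected offset with the same relative bin; both carry weight 1/2. Rotated
    offsets that leave the (2d+1)^2 window are dropped.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    n = len(points)
    bins = theta_bins(points.n_theta)
    dxs, dys, dks = [], [], []
    if n >= 2:
        x = points.x.astype(float)
        y = points.y.astype(float)
        k = points.k
        cont = points.theta  # continuous orientations, if available
        step = np.pi / points.n_theta
        chunk = max(1, int(4_000_000 // max(n, 1)))
        for start in range(0, n, chunk):
            sl = slice(start, min(start + chunk, n))
            dx = x[None, :] - x[sl, None]
            dy = y[None, :] - y[sl, None]
            near = (np.abs(dx) <= d) & (np.abs(dy) <= d)
            rows = np.arange(sl.start, sl.stop)
            near[rows - sl.start, rows] = False
            if not np.any(near):
                continue
            ref, other = np.nonzero(near)
            theta = bins[k[rows[ref]]] if cont is None else cont[rows[ref]]
            rx, ry = rotate_offsets(dx[ref, other], dy[ref, other], theta)
            rx = np.rint(rx).astype(int)
            ry = np.rint(ry).astype(int)
            keep = (np.abs(rx) <= d) & (np.abs(ry) <= d)
            if cont is None:
                dk = np.mod(k[other][keep] - k[rows[ref]][keep], points.n_theta)
            else:
                dtheta = cont[other][keep] - cont[rows[ref]][keep]
                dk = np.mod(np.rint(np.mod(dtheta, np.pi) / step).astype(int), points.n_theta)
            dxs.append(rx[keep])
            dys.append(ry[keep])
            dks.append(dk)
    if dxs:
        dx = np.concatenate(dxs)
        dy = np.concatenate(dys)
        dk = np.concatenate(dks)
        # antipodal representative: point-reflected offset, same relative bin
        dx = np.concatenate([dx, -dx])
        dy = np.concatenate([dy, -dy])
        dk = np.concatenate([dk, dk])
        w = np.full(len(dx), 0.5)
    else:
        dx = dy = dk = np.empty(0, dtype=int)
        w = np.empty(0)
    return ShiftTwistDifferenceSet(
        dx=dx, dy=dy, dk=dk, weight=w, d=d, n_theta=points.n_theta
    )


def accumulate_kernel(
    differences: ShiftTwistDifferenceSet,
    d: int | None = None,
    n_theta: int | None = None,
) -> CooccurrenceKernel:
    """3D histogram of the weighted difference multiset (unnormalized)."""
    d = differences.d if d is None else d
    n_theta = differences.n_theta if n_theta is None else n_theta
    side = 2 * d + 1
    if len(differences):
        if (
            np.any(np.abs(differences.dx) > d)
            or np.any(np.abs(differences.dy) > d)
            or np.any((differences.dk < 0) | (differences.dk >= n_theta))
        ):
            raise ValueError("difference outside kernel bounds")
    values = np.zeros((side, side, n_theta))
    if len(differences):
        flat = (
            (differences.dx + d) * side + (differences.dy + d)
        ) * n_theta + differences.dk
        counts = np.bincount(flat, weights=differences.weight, minlength=side * side * n_theta)
        values = counts.reshape(side, side, n_theta)
    return CooccurrenceKernel(values=values, d=d, n_theta=n_theta, normalized=False)


def normalize_kernel(kernel: CooccurrenceKernel) -> CooccurrenceKernel:
    """l1-normalize so entries sum to 1."""
    total = kernel.values.sum()
    if total <= 0:
        raise ValueError("cannot normalize a zero-mass kernel")
    return CooccurrenceKernel(
        values=kernel.values / total,
        d=kernel.d,
        n_theta=kernel.n_theta,
        normalized=True,
    )


def combine_av_kernels(
    arteries: CooccurrenceKernel, veins: CooccurrenceKernel
) -> CooccurrenceKernel:
    """Entrywise sum of the artery and vein count histograms.

    Arteries never connect directly to veins, so accumulating their pair
    statistics separately and adding the histograms drops exactly the
    cross-label pair contributions.
    """
    if arteries.shape != veins.shape:
        raise ValueError("artery/vein kernel shapes differ")
    if arteries.normalized or veins.normalized:
        raise ValueError("combine unnormalized count kernels, then normalize")
    return CooccurrenceKernel(
        values=arteries.values + veins.values,
        d=arteries.d,
        n_theta=arteries.n_theta,
        normalized=False,
    )


def kernel_distance(
    k1: CooccurrenceKernel | np.ndarray,
    k2: CooccurrenceKernel | np.ndarray,
    symmetric: bool = False,
) -> float:
    """Percent l2 distance between two normalized kernels.

    Returns ``100 * ||k1 - k2||_2 / ||k1||_2`` (or, with ``symmetric=True``,
    normalized by ``max(||k1||_2, ||k2||_2)``). The raw (unnormalized) l2
    difference is available via :func:`kernel_l2`.
    """
    a = k1.values if isinstance(k1, CooccurrenceKernel) else np.asarray(k1)
    b = k2.values if isinstance(k2, CooccurrenceKernel) else np.asarray(k2)
    if a.shape != b.shape:
        raise ValueError(f"kernel shapes differ: {a.shape} vs {b.shape}")
    diff = np.linalg.norm((a - b).ravel())
    if symmetric:
        denom = max(np.linalg.norm(a.ravel()), np.linalg.norm(b.ravel()))
    else:
        denom = np.linalg.norm(a.ravel())
    if denom == 0:
        raise ValueError("zero-norm reference kernel")
    return 100.0 * diff / denom


def kernel_l2(k1, k2) -> float:
    """Raw l2 norm of the kernel difference."""
    a = k1.values if isinstance(k1, CooccurrenceKernel) else np.asarray(k1)
    b = k2.values if isinstance(k2, CooccurrenceKernel) else np.asarray(k2)
    if a.shape != b.shape:
        raise ValueError(f"kernel shapes differ: {a.shape} vs {b.shape}")
    return float(np.linalg.norm((a - b).ravel()))


class LineCooccurrence(BaseEstimator):
    """Estimator learning a statistical line co-occurrence kernel.

    Parameters
    ----------
    d : maximum pairing (Chebyshev) distance in pixels.
    n_theta : number of pi-periodic orientation bins.

    Attributes
    ----------
    kernel_ : CooccurrenceKernel
        The l1-normalized statistical kernel accumulated over all samples.
    counts_ : CooccurrenceKernel
        The unnormalized accumulated counts.
    """

    def __init__(self, d: int = 65, n_theta: int = 16):
        self.d = d
        self.n_theta = n_theta

    def fit(self, X, y=None):
        """Accumulate co-occurrences over samples.

        ``X`` is an iterable of :class:`InterestPointSet`, or of
        ``(centerlines, OrientationMap)`` pairs, or of ``(points_A, points_V)``
        artery/vein-separated pairs of InterestPointSet.
        """
        side = 2 * self.d + 1
        total = np.zeros((side, side, self.n_theta))
        n_samples = 0
        for sample in X:
            for points in self._as_point_sets(sample):
                diffs = shift_twist_differences(points, self.d)
                total += accumulate_kernel(diffs, self.d, self.n_theta).values
            n_samples += 1
        counts = CooccurrenceKernel(total, self.d, self.n_theta, normalized=False)
        self.counts_ = counts
        self.kernel_ = normalize_kernel(counts)
        self.n_samples_ = n_samples
        return self

    def _as_point_sets(self, sample):
        if isinstance(sample, InterestPointSet):
            return [sample]
        a, b = sample
        if isinstance(a, InterestPointSet):
            return [a, b]
        return [build_interest_points(a, b)]
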