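"""Perceptual grouping of segmented vessels.

Every segmentation pixel is lifted to (position, dominant orientation,
normalized intensity). The pairwise affinity combines the connectivity kernel
looked up at the shift-twist difference of the two lifted points with a
Gaussian similarity of their normalized intensities,

    A_final(i, j) = k((x_i, th_i), (x_j, th_j)) * G_sigma(I_n(x_i) - I_n(x_j)),

symmetrized by averaging the two lookup directions. The affinity matrix is
partitioned by self-tuning spectral clustering: the top eigenvectors of the
symmetrically normalized affinity are rotated (Givens rotations, deterministic
gradient-free optimization) toward a maximally sparse indicator structure, and
the group count is the largest candidate whose alignment cost is within
tolerance of the minimum. Small groups are pruned as noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, ClusterMixin

from .cooc import CooccurrenceKernel
from .oscore import dominant_orientations, make_cake_wavelets, orientation_score
from .utils import rotate_offsets, theta_bins

__all__ = [
    "LiftedPointSet",
    "AffinityMatrix",
    "ClusterLabels",
    "normalize_retinal_intensity",
    "build_affinity",
    "cluster_self_tuning",
    "prune_small_groups",
    "group_vessels",
    "SelfTuningSpectralClustering",
    "VesselGrouper",
]


@dataclass
class LiftedPointSet:
    """Segmentation pixels lifted to (x, y, orientation bin, intensity)."""

    x: np.ndarray
    y: np.ndarray
    k: np.ndarray
    intensity: np.ndarray
    n_theta: int

    @property
    def m(self) -> int:
        return len(self.x)


@dataclass
class AffinityMatrix:
    """Symmetric nonnegative m x m affinity with zero diagonal."""

    values: np.ndarray
    sigma_int: float


@dataclass
class ClusterLabels:
    """Per-point group labels; -1 marks pruned/noise points."""

    labels: np.ndarray
    n_groups: int


def normalize_retinal_intensity(image: np.ndarray, background_scale: float = 15.0) -> np.ndarray:
    """Local luminosity/contrast normalization, rescaled to [0, 1].

    Subtracts a large-scale Gaussian mean and divides by the matching local
    standard deviation, which removes smooth illumination bias fields; the
    result is affinely rescaled to [0, 1] using robust (0.5/99.5 percentile)
    anchors so single extreme pixels do not set the scale.
    """
    image = np.asarray(image, dtype=float)
    mu = gaussian_filter(image, background_scale)
    var = gaussian_filter((image - mu) ** 2, background_scale)
    sd = np.sqrt(var)
    if float(sd.max()) < 1e-10:
        raise ValueError("constant image: local contrast is zero")
    z = (image - mu) / np.maximum(sd, 1e-3 * sd.max())
    lo, hi = np.percentile(z, [0.5, 99.5])
    return np.clip((z - lo) / (hi - lo), 0.0, 1.0)


def build_affinity(
    points: LiftedPointSet,
    kernel: CooccurrenceKernel,
    sigma_int: float = 0.2,
) -> AffinityMatrix:
    """Connectivity x intensity affinity over all point pairs.

    The connectivity factor is the kernel bin of the shift-twist difference,
    averaged over the two lookup directions so the matrix is exactly
    symmetric; pairs beyond the kernel's spatial support get zero, and the
    diagonal is zero.
    """
    if sigma_int <= 0:
        raise ValueError("sigma_int must be > 0")
    if points.n_theta != kernel.n_theta:
        raise ValueError("point set and kernel disagree on n_theta")
    d = kernel.d
    bins = theta_bins(points.n_theta)
    x = points.x.astype(float)
    y = points.y.astype(float)
    dxm = x[None, :] - x[:, None]
    dym = y[None, :] - y[:, None]
    theta_i = bins[points.k][:, None]
    rx, ry = rotate_offsets(dxm, dym, theta_i)
    rx = np.rint(rx).astype(int)
    ry = np.rint(ry).astype(int)
    inside = (np.abs(rx) <= d) & (np.abs(ry) <= d)
    dk = np.mod(points.k[None, :] - points.k[:, None], points.n_theta)
    conn = np.zeros_like(dxm)
    conn[inside] = kernel.values[rx[inside] + d, ry[inside] + d, dk[inside]]
    conn = 0.5 * (conn + conn.T)

    di = points.intensity[None, :] - points.intensity[:, None]
    gauss = np.exp(-(di**2) / (2.0 * sigma_int**2)) / (sigma_int * np.sqrt(2 * np.pi))
    values = conn * gauss
    np.fill_diagonal(values, 0.0)
    return AffinityMatrix(values=values, sigma_int=sigma_int)


# ---------------------------------------------------------------------------
# self-tuning spectral clustering (automatic group count by eigenvector
# rotation toward a sparse indicator structure)
# ---------------------------------------------------------------------------


def _givens_product(angles: np.ndarray, pairs: list, c: int) -> np.ndarray:
    rot = np.eye(c)
    for (i, j), a in zip(pairs, angles):
        g = np.eye(c)
        ca, sa = np.cos(a), np.sin(a)
        g[i, i] = ca
        g[j, j] = ca
        g[i, j] = -sa
        g[j, i] = sa
        rot = rot @ g
    return rot


def _alignment_cost(z: np.ndarray) -> float:
    z2 = z**2
    m = z2.max(axis=1)
    dead = m < 1e-24  # rows invisible in this subspace cannot be assigned
    m = np.maximum(m, 1e-300)
    cost = (z2 / m[:, None]).sum(axis=1)
    cost[dead] = z.shape[1]  # worst possible per-row value
    return float(cost.sum())


def _pairs(c: int) -> list:
    return [(i, j) for j in range(1, c) for i in range(j)]


def cluster_self_tuning(
    affinity: AffinityMatrix | np.ndarray,
    max_groups: int = 10,
    cost_tol: float = 0.01,
) -> ClusterLabels:
    """Partition an affinity matrix, choosing the group count automatically.

    The symmetrically normalized affinity's top ``max_groups`` eigenvectors
    are aligned, per candidate count C, with the sparsest rotation found by
    deterministic optimization over Givens angles (warm-started from the
    C - 1 solution). The selected C is the largest whose alignment cost is
    within ``cost_tol`` (relative) of the minimum; C = 1 is included with the
    ideal cost, so structureless affinities collapse to a single group.
    All-zero rows are pre-assigned the noise label -1.
    """
    a = affinity.values if isinstance(affinity, AffinityMatrix) else np.asarray(affinity)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("affinity must be square")
    if a.shape[0] < 2 or max_groups < 2:
        raise ValueError("need at least 2 points and max_groups >= 2")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("affinity must be symmetric")
    if a.min() < 0:
        raise ValueError("affinity must be nonnegative")

    m = a.shape[0]
    labels = np.full(m, -1, dtype=int)
    deg = a.sum(axis=1)
    active = deg > 0
    idx = np.nonzero(active)[0]
    if len(idx) == 0:
        return ClusterLabels(labels=labels, n_groups=0)
    if len(idx) == 1:
        labels[idx] = 0
        return ClusterLabels(labels=labels, n_groups=1)

    sub = a[np.ix_(idx, idx)]
    dsq = 1.0 / np.sqrt(sub.sum(axis=1))
    lsym = dsq[:, None] * sub * dsq[None, :]
    evals, evecs = np.linalg.eigh(lsym)
    order = np.argsort(evals)[::-1]
    n_cand = min(max_groups, len(idx))
    basis = evecs[:, order[:n_cand]]
    # deterministic sign convention
    signs = np.sign(basis[np.argmax(np.abs(basis), axis=0), np.arange(n_cand)])
    signs[signs == 0] = 1.0
    basis = basis * signs

    n_active = len(idx)
    costs = {1: float(n_active)}
    rotations = {}
    prev_angles = np.empty(0)
    for c in range(2, n_cand + 1):
        pairs = _pairs(c)
        xc = basis[:, :c]

        def cost(angles, pairs=pairs, c=c, xc=xc):
            return _alignment_cost(xc @ _givens_product(angles, pairs, c))

        # deterministic multi-start: warm start from the c-1 alignment plus a
        # few fixed-angle inits, keep the sparsest result
        starts = [np.zeros(len(pairs))]
        starts[0][: len(prev_angles)] = prev_angles
        starts.append(np.zeros(len(pairs)))
        starts.append(np.full(len(pairs), np.pi / 4))
        starts.append(np.full(len(pairs), -np.pi / 4))
        best = None
        for x0 in starts:
            res = minimize(cost, x0, method="L-BFGS-B", options={"maxiter": 500})
            if best is None or res.fun < best.fun:
                best = res
        prev_angles = best.x
        costs[c] = float(best.fun)
        rotations[c] = _givens_product(best.x, pairs, c)

    best = min(costs.values())
    chosen = max(cc for cc, v in costs.items() if v <= (1.0 + cost_tol) * best)
    if chosen == 1:
        labels[idx] = 0
        return ClusterLabels(labels=labels, n_groups=1)
    z = basis[:, :chosen] @ rotations[chosen]
    assign = np.argmax(z**2, axis=1)
    # relabel contiguously in order of first appearance
    uniq, first = np.unique(assign, return_index=True)
    remap = {int(u): r for r, u in enumerate(uniq[np.argsort(first)])}
    labels[idx] = [remap[int(v)] for v in assign]
    return ClusterLabels(labels=labels, n_groups=len(uniq))


def prune_small_groups(labels: ClusterLabels, min_size: int = 10) -> ClusterLabels:
    """Groups smaller than ``min_size`` become noise (-1); survivors are
    relabeled contiguously."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    out = labels.labels.copy()
    kept = []
    for g in range(labels.n_groups):
        size = int(np.sum(out == g))
        if size and size < min_size:
            out[out == g] = -1
        elif size:
            kept.append(g)
    for new, old in enumerate(kept):
        out[labels.labels == old] = new
    return ClusterLabels(labels=out, n_groups=len(kept))


def group_vessels(
    image: np.ndarray,
    segmentation: np.ndarray,
    kernel: CooccurrenceKernel,
    sigma_int: float = 0.2,
    max_groups: int = 10,
    min_size: int | None = None,
    background_scale: float = 15.0,
    wavelet_size: int | None = None,
    wavelets=None,
):
    """End-to-end grouping of a segmented patch.

    Lifts all segmentation pixels (not only centerlines), normalizes the
    intensity, builds the combined affinity, clusters it and prunes small
    groups. Returns ``(label_map, ClusterLabels, LiftedPointSet)`` where the
    label map is image-shaped with -1 on background and pruned pixels.
    """
    image = np.asarray(image, dtype=float)
    segmentation = np.asarray(segmentation).astype(bool)
    if segmentation.shape != image.shape:
        raise ValueError("image and segmentation shapes differ")
    if not segmentation.any():
        raise ValueError("empty segmentation")
    if not kernel.normalized:
        raise ValueError("kernel must be normalized")

    if wavelets is None:
        if wavelet_size is None:
            wavelet_size = min(51, min(image.shape))
            if wavelet_size % 2 == 0:
                wavelet_size -= 1
        wavelets = make_cake_wavelets(kernel.n_theta, wavelet_size)
    score = orientation_score(image, wavelets)
    omap = dominant_orientations(score, segmentation)
    normalized = normalize_retinal_intensity(image, background_scale)

    rows, cols = np.nonzero(segmentation)
    points = LiftedPointSet(
        x=cols.astype(int),
        y=rows.astype(int),
        k=omap.angle_index[rows, cols].astype(int),
        intensity=normalized[rows, cols],
        n_theta=kernel.n_theta,
    )
    affinity = build_affinity(points, kernel, sigma_int)
    raw = cluster_self_tuning(affinity, max_groups=max_groups)
    if min_size is None:
        min_size = max(10, int(0.01 * points.m))
    pruned = prune_small_groups(raw, min_size)

    label_map = np.full(image.shape, -1, dtype=int)
    label_map[rows, cols] = pruned.labels
    return label_map, pruned, points


class SelfTuningSpectralClustering(BaseEstimator, ClusterMixin):
    """sklearn-style wrapper around :func:`cluster_self_tuning`.

    ``fit(A)`` expects a precomputed symmetric nonnegative affinity; fitted
    attributes are ``labels_`` and ``n_groups_``.
    """

    def __init__(self, max_groups: int = 10, cost_tol: float = 0.01):
        self.max_groups = max_groups
        self.cost_tol = cost_tol

    def fit(self, X, y=None):
        res = cluster_self_tuning(X, self.max_groups, self.cost_tol)
        self.labels_ = res.labels
        self.n_groups_ = res.n_groups
        return self


class VesselGrouper(BaseEstimator, ClusterMixin):
    """End-to-end vessel grouper (sklearn-style).

    Parameters mirror :func:`group_vessels`; ``fit(image, segmentation)``
    exposes ``labels_`` (per lifted point), ``label_map_`` (image-shaped) and
    ``n_groups_``.
    """

    def __init__(
        self,
        kernel: CooccurrenceKernel = None,
        sigma_int: float = 0.2,
        max_groups: int = 10,
        min_size: int | None = None,
        background_scale: float = 15.0,
        wavelet_size: int | None = None,
    ):
        self.kernel = kernel
        self.sigma_int = sigma_int
        self.max_groups = max_groups
        self.min_size = min_size
        self.background_scale = background_scale
        self.wavelet_size = wavelet_size

    def fit(self, X, y=None):
        image, segmentation = X
        label_map, labels, points = group_vessels(
            image,
            segmentation,
            self.kernel,
            sigma_int=self.sigma_int,
            max_groups=self.max_groups,
            min_size=self.min_size,
            background_scale=self.background_scale,
            wavelet_size=self.wavelet_size,
        )
        self.label_map_ = label_map
        self.labels_ = labels.labels
        self.n_groups_ = labels.n_groups
        self.points_ = points
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).label_map_
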