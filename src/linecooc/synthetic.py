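"""Synthetic inputs: direction-process sample paths and vessel phantoms.

Two generators cover the package's test surface:

* :func:`sample_direction_paths` draws trajectories of Mumford's direction
  process (the same dynamics as the Monte-Carlo resolvent oracle, but keeping
  the whole trajectory) and rasterizes them to 1-px centerlines with the true
  tangent orientation at every pixel. Co-occurrence statistics learned from
  these paths are, by construction, draws from the resolvent model: the gap
  between two points of a path with lifetime T ~ Exp(alpha) is exponentially
  weighted by memorylessness, which is exactly the resolvent's time weighting.

* :func:`make_phantom` renders crossing / bifurcating / parallel /
  interrupted vessel phantoms (anti-aliased bands of configurable width, mean
  intensity and gap intervals, dark on a bright background, plus Gaussian
  noise) with per-pixel ground-truth group labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
from scipy.spatial import cKDTree

from .connectivity import DirectionProcessParams
from .cooc import InterestPointSet
from .utils import angle_to_bin

__all__ = [
    "Curve",
    "PhantomSpec",
    "SyntheticSample",
    "PathSample",
    "sample_direction_paths",
    "paths_to_point_sets",
    "make_phantom",
    "phantom_preset",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# direction-process paths
# ---------------------------------------------------------------------------


@dataclass
class PathSample:
    """A rasterized trajectory: pixel polyline with true tangents."""

    pixels: np.ndarray   # (L, 2) int, columns (x, y), consecutive-deduped
    tangents: np.ndarray  # (L,) tangent angle (radians, 2*pi-periodic)


def sample_direction_paths(
    params: DirectionProcessParams,
    n_paths: int,
    seed: int = 0,
    canvas: int | None = None,
    dt: float = 0.1,
) -> tuple[list[PathSample], np.ndarray | None]:
    """Sample direction-process trajectories rasterized to 1-px centerlines.

    Without a canvas, every path starts at the origin with tangent 0 (the
    frame used by the resolvent kernels). With ``canvas`` (side length in px),
    starts and initial directions are uniform over the canvas and the circle,
    paths are clipped to the canvas, and a combined centerline mask is
    returned; a canvas smaller than the mean path length 1/alpha is allowed
    but logged as a warning.
    """
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if canvas is not None and canvas < 1.0 / params.alpha:
        log.warning(
            "canvas %d px is smaller than the mean path length %.1f px; "
            "paths will be clipped",
            canvas,
            1.0 / params.alpha,
        )
    rng = np.random.default_rng(seed)
    sigma = params.sigma
    paths: list[PathSample] = []
    mask = np.zeros((canvas, canvas), dtype=np.uint8) if canvas is not None else None

    for _ in range(n_paths):
        T = rng.exponential(1.0 / params.alpha)
        n = int(T // dt)
        rem = T - n * dt
        if canvas is not None:
            x0, y0 = rng.uniform(0, canvas - 1, 2)
            th0 = rng.uniform(0, 2 * np.pi)
        else:
            x0 = y0 = 0.0
            th0 = 0.0
        incr = sigma * np.sqrt(dt) * rng.standard_normal(n)
        theta = th0 + np.concatenate(([0.0], np.cumsum(incr)))  # (n+1,)
        x = x0 + dt * np.concatenate(([0.0], np.cumsum(np.cos(theta[:-1]))))
        y = y0 + dt * np.concatenate(([0.0], np.cumsum(np.sin(theta[:-1]))))
        # final partial step with the last tangent
        x = np.append(x, x[-1] + rem * np.cos(theta[-1]))
        y = np.append(y, y[-1] + rem * np.sin(theta[-1]))
        theta = np.append(theta, theta[-1])

        # sample at ~unit arc spacing before rounding: a finer trace would
        # emit boundary-flicker duplicates next to the centerline, which a
        # morphologically thinned skeleton never contains
        stride = max(1, int(round(1.0 / dt)))
        sel = np.arange(0, len(x), stride)
        if sel[-1] != len(x) - 1:
            sel = np.append(sel, len(x) - 1)
        px = np.rint(np.column_stack([x[sel], y[sel]])).astype(int)
        change = np.ones(len(px), dtype=bool)
        change[1:] = np.any(px[1:] != px[:-1], axis=1)
        px = px[change]
        tang = theta[sel][change]
        if canvas is not None:
            inside = (
                (px[:, 0] >= 0)
                & (px[:, 0] < canvas)
                & (px[:, 1] >= 0)
                & (px[:, 1] < canvas)
            )
            px, tang = px[inside], tang[inside]
            if mask is not None and len(px):
                mask[px[:, 1], px[:, 0]] = 1
        paths.append(PathSample(pixels=px, tangents=tang))
    return paths, mask


def paths_to_point_sets(paths: list[PathSample], n_theta: int) -> list[InterestPointSet]:
    """Interest points per path from true tangents (unique pixels, first visit)."""
    sets = []
    for p in paths:
        if len(p.pixels) == 0:
            sets.append(
                InterestPointSet(
                    x=np.empty(0, int), y=np.empty(0, int), k=np.empty(0, int), n_theta=n_theta
                )
            )
            continue
        _, first = np.unique(
            p.pixels[:, 0] * 2_000_003 + p.pixels[:, 1], return_index=True
        )
        first.sort()
        px = p.pixels[first]
        tang = p.tangents[first]
        k = angle_to_bin(tang, n_theta)
        sets.append(
            InterestPointSet(
                x=px[:, 0], y=px[:, 1], k=k, n_theta=n_theta, theta=tang
            )
        )
    return sets


# ---------------------------------------------------------------------------
# vessel phantoms
# ---------------------------------------------------------------------------


@dataclass
class Curve:
    """A parametric curve: 'line' (p0, p1), 'arc' (center, radius, angles) or
    'poly' (x range + polynomial coefficients for y(x), ascending order)."""

    kind: str
    params: tuple
    width: float = 3.0
    intensity: float = 0.3
    gaps: tuple = ()  # arc-length intervals (s0, s1) removed from the band

    def sample(self, step: float = 0.25) -> np.ndarray:
        """Dense (x, y) samples along the curve at ~step px spacing."""
        if self.kind == "line":
            (x0, y0), (x1, y1) = self.params
            length = float(np.hypot(x1 - x0, y1 - y0))
            t = np.linspace(0.0, 1.0, max(int(length / step), 2))
            pts = np.column_stack([x0 + t * (x1 - x0), y0 + t * (y1 - y0)])
        elif self.kind == "arc":
            (cx, cy), radius, (a0, a1) = self.params
            length = abs(a1 - a0) * radius
            t = np.linspace(a0, a1, max(int(length / step), 2))
            pts = np.column_stack([cx + radius * np.cos(t), cy + radius * np.sin(t)])
        elif self.kind == "poly":
            (x0, x1), coeffs = self.params
            xs = np.linspace(x0, x1, max(int(abs(x1 - x0) / (step / 2)), 2))
            ys = np.polynomial.polynomial.polyval(xs, coeffs)
            pts = np.column_stack([xs, ys])
        else:
            raise ValueError(f"unknown curve kind {self.kind!r}")
        return pts


@dataclass
class PhantomSpec:
    size: int
    curves: list
    noise_sigma: float = 0.02
    background: float = 0.85
    seed: int = 0


@dataclass
class SyntheticSample:
    """Phantom image with masks and ground-truth labels.

    ``labels`` is 0 on background and ``i + 1`` on pixels of curve ``i``
    (first-listed curve wins on overlaps); ``overlap`` marks pixels covered by
    more than one curve (excluded when scoring label agreement).
    """

    image: np.ndarray
    segmentation: np.ndarray
    centerlines: np.ndarray
    labels: np.ndarray
    overlap: np.ndarray
    spec: PhantomSpec = None


def _arclength(pts: np.ndarray) -> np.ndarray:
    seg = np.hypot(*np.diff(pts, axis=0).T)
    return np.concatenate(([0.0], np.cumsum(seg)))


def make_phantom(spec: PhantomSpec) -> SyntheticSample:
    """Render the phantom described by ``spec``."""
    for i, a in enumerate(spec.curves):
        for b in spec.curves[i + 1 :]:
            if a.kind == b.kind and a.params == b.params:
                raise ValueError("identical curves in phantom spec")
    size = spec.size
    yy, xx = np.mgrid[0:size, 0:size]
    grid = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)

    coverage = []  # per curve: anti-aliased coverage in [0, 1]
    centers = []   # per curve: centerline pixels (int)
    for curve in spec.curves:
        pts = curve.sample()
        s = _arclength(pts)
        keep = np.ones(len(pts), dtype=bool)
        for s0, s1 in curve.gaps:
            keep &= ~((s >= s0) & (s <= s1))
        pts = pts[keep]
        cov = np.zeros(size * size)
        if len(pts):
            tree = cKDTree(pts)
            dist, _ = tree.query(grid, k=1, distance_upper_bound=curve.width / 2 + 1.5)
            cov = np.clip(curve.width / 2 + 0.5 - dist, 0.0, 1.0)
            cov[~np.isfinite(dist)] = 0.0
        coverage.append(cov.reshape(size, size))
        cpx = np.rint(pts).astype(int)
        if len(cpx):
            inside = (
                (cpx[:, 0] >= 0) & (cpx[:, 0] < size) & (cpx[:, 1] >= 0) & (cpx[:, 1] < size)
            )
            cpx = np.unique(cpx[inside], axis=0)
        centers.append(cpx)

    image = np.full((size, size), spec.background)
    for cov, curve in zip(reversed(coverage), reversed(spec.curves)):
        image = image * (1 - cov) + curve.intensity * cov  # first-listed painted last

    hard = [cov >= 0.5 for cov in coverage]
    segmentation = np.zeros((size, size), dtype=np.uint8)
    labels = np.zeros((size, size), dtype=int)
    counts = np.zeros((size, size), dtype=int)
    for i, h in enumerate(hard):
        segmentation[h] = 1
        counts += h.astype(int)
        labels[h & (labels == 0)] = i + 1
    overlap = counts > 1

    centerlines = np.zeros((size, size), dtype=np.uint8)
    for cpx in centers:
        if len(cpx):
            centerlines[cpx[:, 1], cpx[:, 0]] = 1
    centerlines &= segmentation  # band edges clipped by gaps stay consistent

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, image.shape)
    image = np.clip(image, 0.0, 1.0)

    return SyntheticSample(
        image=image,
        segmentation=segmentation,
        centerlines=centerlines,
        labels=labels,
        overlap=overlap,
        spec=spec,
    )


def phantom_preset(
    kind: str,
    size: int = 101,
    seed: int = 0,
    intensities: tuple = (0.3, 0.7),
    width: float = 3.0,
    noise_sigma: float = 0.02,
    gap: float = 5.0,
) -> SyntheticSample:
    """Seeded phantoms for the four structure classes: 'crossing',
    'bifurcation', 'parallel' and 'interrupted'."""
    s = size - 1
    i0, i1 = intensities
    if kind == "crossing":
        curves = [
            Curve("line", ((0.05 * s, 0.30 * s), (0.95 * s, 0.70 * s)), width, i0),
            Curve("line", ((0.20 * s, 0.95 * s), (0.80 * s, 0.05 * s)), width, i1),
        ]
    elif kind == "bifurcation":
        curves = [
            Curve("line", ((0.50 * s, 0.05 * s), (0.50 * s, 0.95 * s)), width, i0),
            Curve("line", ((0.52 * s, 0.50 * s), (0.95 * s, 0.88 * s)), width, i1),
        ]
    elif kind == "parallel":
        curves = [
            Curve("line", ((0.05 * s, 0.35 * s), (0.95 * s, 0.55 * s)), width, i0),
            Curve("line", ((0.05 * s, 0.45 * s), (0.95 * s, 0.65 * s)), width, i1),
        ]
    elif kind == "interrupted":
        (x0, y0), (x1, y1) = (0.10 * s, 0.30 * s), (0.90 * s, 0.70 * s)
        length = float(np.hypot(x1 - x0, y1 - y0))
        curves = [
            Curve(
                "line",
                ((x0, y0), (x1, y1)),
                width,
                i0,
                gaps=((length / 2 - gap / 2, length / 2 + gap / 2),),
            )
        ]
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")
    return make_phantom(
        PhantomSpec(size=size, curves=curves, noise_sigma=noise_sigma, seed=seed)
    )
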