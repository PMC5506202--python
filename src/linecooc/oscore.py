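"""Orientation scores via cake wavelets.

An image is lifted to positions x (pi-periodic) orientations by correlating
with a stack of rotated, bi-directional cake wavelets. The wavelets are built
in the Fourier domain: each filter is a pair of antipodal angular wedges (a
periodized cardinal B-spline profile) multiplied by a radial pass band that
removes the DC component and tapers off below the Nyquist frequency. Because
the B-spline wedges form a partition of unity over the circle, the summed
spectra of the stack equal 1 on the pass annulus, so the decomposition treats
all line widths inside the band equally.

Vessels are darker than the retinal background, so the real part of the score
acts as a ridge detector with large *negative* values on vessels; the dominant
orientation at a pixel is the argmax over theta of the negated real part.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.signal import fftconvolve
from scipy.special import erfc

from .utils import theta_bins

__all__ = [
    "WaveletStack",
    "OrientationScore",
    "OrientationMap",
    "make_cake_wavelets",
    "orientation_score",
    "dominant_orientations",
]


@dataclass
class WaveletStack:
    """A stack of ``n_theta`` complex cake wavelets of odd size ``size``."""

    filters: np.ndarray  # (n_theta, size, size) complex
    n_theta: int
    size: int
    theta_bins: np.ndarray = field(default=None)
    dc_radius: float = 0.0      # cycles/px; pass annulus inner edge
    taper_radius: float = 0.5   # cycles/px; pass annulus outer edge

    def __post_init__(self):
        if self.theta_bins is None:
            self.theta_bins = theta_bins(self.n_theta)


@dataclass
class OrientationScore:
    """Complex score ``values[row, col, k]`` for orientation bin ``k``."""

    values: np.ndarray
    theta_bins: np.ndarray

    @property
    def n_theta(self) -> int:
        return self.values.shape[2]


@dataclass
class OrientationMap:
    """Per-pixel dominant orientation bin where ``defined_mask`` is true."""

    angle_index: np.ndarray
    defined_mask: np.ndarray
    theta_bins: np.ndarray

    @property
    def n_theta(self) -> int:
        return len(self.theta_bins)


def _cardinal_bspline(order: int):
    """Cardinal B-spline of ``order`` supported on [-(order+1)/2, (order+1)/2]."""
    knots = np.arange(order + 2, dtype=float) - (order + 1) / 2.0
    return BSpline.basis_element(knots, extrapolate=False)


def make_cake_wavelets(
    n_theta: int,
    size: int,
    angular_order: int = 3,
    nyquist_taper: float = 0.9,
    dc_sigma: float = 0.02,
) -> WaveletStack:
    """Build ``n_theta`` bi-directional cake wavelets of odd ``size``.

    Parameters
    ----------
    n_theta : number of pi-periodic orientation bins.
    size : odd spatial support of the filters, in pixels.
    angular_order : order of the B-spline angular profile.
    nyquist_taper : fraction of the Nyquist frequency at which the radial
        roll-off starts; the pass annulus is [dc-exclusion radius, onset].
    dc_sigma : sigma (cycles/px) of the Gaussian DC notch; the DC-exclusion
        radius is ``8 * dc_sigma``.

    The summed Fourier spectra of the stack equal 1 (to ~1e-8) on the pass
    annulus, and each filter has zero mean, so a constant image produces no
    directional response.
    """
    if size % 2 == 0:
        raise ValueError("wavelet size must be odd")
    if n_theta < 1:
        raise ValueError("n_theta must be >= 1")
    if not 0 < nyquist_taper <= 1:
        raise ValueError("nyquist_taper must lie in (0, 1]")

    fx = np.fft.fftfreq(size)  # cycles/px
    wx, wy = np.meshgrid(fx, fx, indexing="xy")  # wx varies along columns
    rho = np.hypot(wx, wy)
    phi = np.arctan2(wy, wx)

    nyq = 0.5
    onset = nyquist_taper * nyq
    # erf-style roll-off: ~1 at the onset, ~0 at Nyquist.
    mid = 0.5 * (onset + nyq)
    width = max((nyq - onset) / 8.0, 1e-6)
    taper = 0.5 * erfc((rho - mid) / width)
    notch = np.exp(-(rho**2) / (2.0 * dc_sigma**2))
    radial = (1.0 - notch) * taper

    # 2*n_theta full-circle wedges; bi-directional filter k sums the antipodal
    # pair. Wedge centers sit at theta_k + pi/2 because a line oriented along
    # theta has its spectrum on the perpendicular line through the origin.
    n_full = 2 * n_theta
    s_theta = 2 * np.pi / n_full
    spline = _cardinal_bspline(angular_order)
    half_support = (angular_order + 1) / 2.0
    bins = theta_bins(n_theta)

    filters = np.empty((n_theta, size, size), dtype=complex)
    for k in range(n_theta):
        wedge = np.zeros_like(rho)
        for center in (bins[k] + np.pi / 2, bins[k] + 3 * np.pi / 2):
            diff = np.mod(phi - center + np.pi, 2 * np.pi) - np.pi
            # periodize the B-spline profile over the circle
            for m in (-1, 0, 1):
                arg = (diff + 2 * np.pi * m) / s_theta
                inside = np.abs(arg) <= half_support
                if np.any(inside):
                    vals = spline(arg[inside])
                    wedge[inside] += np.nan_to_num(vals)
        spectrum = wedge * radial
        filters[k] = np.fft.fftshift(np.fft.ifft2(spectrum))

    return WaveletStack(
        filters=filters,
        n_theta=n_theta,
        size=size,
        theta_bins=bins,
        dc_radius=8.0 * dc_sigma,
        taper_radius=onset,
    )


def stack_spectrum_sum(stack: WaveletStack) -> np.ndarray:
    """Sum over orientations of the filters' Fourier spectra (fftshifted)."""
    spectra = np.fft.fft2(np.fft.ifftshift(stack.filters, axes=(1, 2)), axes=(1, 2))
    return np.fft.fftshift(spectra.sum(axis=0))


def pass_annulus_mask(stack: WaveletStack) -> np.ndarray:
    """Boolean frequency mask of the pass annulus (fftshifted layout)."""
    fx = np.fft.fftshift(np.fft.fftfreq(stack.size))
    wx, wy = np.meshgrid(fx, fx, indexing="xy")
    rho = np.hypot(wx, wy)
    return (rho >= stack.dc_radius) & (rho <= stack.taper_radius)


def orientation_score(image: np.ndarray, wavelets: WaveletStack) -> OrientationScore:
    """Correlate ``image`` with the conjugated rotated wavelets.

    The border is handled by reflective padding, so a 51x51 patch can be
    scored with a 51x51 filter without wrap-around artifacts.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D grayscale")
    if wavelets.size > min(image.shape):
        raise ValueError(
            f"wavelet size {wavelets.size} exceeds image dims {image.shape}"
        )
    half = wavelets.size // 2
    padded = np.pad(image, half, mode="reflect")
    values = np.empty(image.shape + (wavelets.n_theta,), dtype=complex)
    for k in range(wavelets.n_theta):
        # correlation with conj(psi) == convolution with conj(psi) flipped
        kern = np.conj(wavelets.filters[k])[::-1, ::-1]
        values[:, :, k] = fftconvolve(padded, kern, mode="valid")
    return OrientationScore(values=values, theta_bins=wavelets.theta_bins)


def dominant_orientations(score: OrientationScore, mask: np.ndarray) -> OrientationMap:
    """Argmax over theta of the negated real part, on ``mask`` pixels.

    Dark lines on a bright background give large negative real responses, so
    the negation selects the orientation of the underlying line. Ties break
    toward the lowest bin index.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != score.values.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match score {score.values.shape[:2]}"
        )
    response = -np.real(score.values)
    angle_index = np.argmax(response, axis=2)
    angle_index = np.where(mask, angle_index, -1)
    return OrientationMap(
        angle_index=angle_index, defined_mask=mask, theta_bins=score.theta_bins
    )
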