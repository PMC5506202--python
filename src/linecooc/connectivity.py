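"""Direction-process (Fokker-Planck) connectivity kernels.

Mumford's direction process moves with unit speed along its current
orientation while the orientation diffuses as Brownian motion with diffusion
constant D33 = sigma^2/2. At an exponentially distributed lifetime
T ~ Exp(alpha) the process stops; the law of the stopped endpoint is the
resolvent kernel

    R_alpha = alpha * Integral_0^inf K_t exp(-alpha t) dt,

the solution of (alpha I - A) R = alpha delta_e with generator
A = -cos(theta) d/dx - sin(theta) d/dy + D33 d^2/dtheta^2.

The numeric solver works in the spatial Fourier domain (the transport term is
diagonal per frequency) with a periodic second-difference Laplacian over 2 *
n_theta orientation samples of [0, 2*pi); each frequency yields a cyclic
tridiagonal system solved in O(n_theta). The spatial domain is periodically
padded and supersampled so that wrap-around and Gibbs ringing stay below the
nonnegativity floor. A Monte-Carlo path simulation provides an independent
oracle.

Projective symmetrization (positions x pi-periodic orientations) uses the
exact time-reversal identity of the direction process,

    R(g^{-1}) = R(-x, -y, theta),

so the four-term forward/backward + pi-shift average reduces to a spatial
point reflection plus a pi bin-roll, both exact on the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import scipy.fft
from sklearn.base import BaseEstimator

from .cooc import CooccurrenceKernel, kernel_distance

log = logging.getLogger(__name__)

__all__ = [
    "DirectionProcessParams",
    "ResolventKernel",
    "ProjectiveKernel",
    "FitResult",
    "fp_resolvent_numeric",
    "fp_resolvent_series",
    "mc_resolvent",
    "mc_resolvent_blurred",
    "symmetrize_projective",
    "xy_marginal",
    "projective_model_kernel",
    "fit_kernel",
    "DirectionProcessFit",
]


@dataclass
class DirectionProcessParams:
    """Decay rate alpha (1/px of travel), angular diffusion D33 (rad^2/px),
    and the spatial Gaussian blur sigma (px) emulating the one-pixel bin."""

    alpha: float
    d33: float
    blur_s: float = 0.5

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.d33 < 0:
            raise ValueError("D33 must be >= 0")
        if self.blur_s < 0:
            raise ValueError("blur_s must be >= 0")

    @property
    def sigma(self) -> float:
        """Angular noise amplitude: sigma = sqrt(2 * D33)."""
        return float(np.sqrt(2.0 * self.d33))


@dataclass
class ResolventKernel:
    """Resolvent on the full circle: (2d+1, 2d+1, 2*n_theta) array.

    Axis 0 is dx + d, axis 1 dy + d; theta layer j holds angle j*pi/n_theta
    over [0, 2*pi) relative to the start direction (layer 0).
    """

    values: np.ndarray
    d: int
    n_theta: int  # projective bin count; the theta axis has 2*n_theta layers
    params: DirectionProcessParams
    mass_total: float = 1.0       # mass on the full (padded) domain
    mass_cropped: float = 0.0     # mass lost by cropping to the window
    renormalized: bool = False
    min_value: float = 0.0        # most negative raw entry (ringing diagnostic)

    @property
    def n_theta_full(self) -> int:
        return self.values.shape[2]


@dataclass
class ProjectiveKernel:
    """Symmetrized kernel on positions x P^1, stored pi-periodically on the
    same 2*n_theta grid as the resolvent it came from."""

    values: np.ndarray
    d: int
    n_theta: int
    params: DirectionProcessParams = None

    def fold(self) -> CooccurrenceKernel:
        """Collapse the pi-periodic duplicate layers to n_theta bins.

        Layer j of the result holds relative orientation j*pi/n_theta; total
        mass is preserved.
        """
        n = self.n_theta
        folded = self.values[:, :, :n] + self.values[:, :, n:]
        return CooccurrenceKernel(folded, d=self.d, n_theta=n, normalized=False)


@dataclass
class FitResult:
    """Best (alpha, D33) and the full least-squares error surface (percent)."""

    best_alpha: float
    best_d33: float
    error_percent: float
    error_surface: np.ndarray  # (len(alpha_grid), len(d33_grid))
    alpha_grid: np.ndarray
    d33_grid: np.ndarray


def _solve_cyclic_tridiagonal(diag: np.ndarray, off: float, rhs: np.ndarray) -> np.ndarray:
    """Solve (diag_j + off*(cyclic shift +/- 1)) x = rhs for each row.

    ``diag`` is (n_sys, n) complex, ``off`` a real constant sub/super-diagonal,
    ``rhs`` broadcastable to (n_sys, n). Strict diagonal dominance
    (Re(diag) > 2*|off|) makes the Thomas sweep stable without pivoting; the
    cyclic corners are handled with a Sherman-Morrison correction.
    """
    n_sys, n = diag.shape
    if off == 0.0:
        return rhs / diag
    rhs_row = np.broadcast_to(rhs, diag.shape)
    out = np.empty_like(diag)
    # chunk the systems so each Thomas sweep stays cache-resident
    chunk = 4096
    for lo in range(0, n_sys, chunk):
        sl = slice(lo, min(lo + chunk, n_sys))
        dg = np.ascontiguousarray(diag[sl].T)  # (n, m)
        r = np.ascontiguousarray(rhs_row[sl].T)
        gamma = -dg[0]  # per-system corner shift
        b = dg
        b[0] -= gamma
        b[-1] -= off * off / gamma

        # two simultaneous Thomas solves: y (rhs) and z (corner correction u)
        u = np.zeros_like(dg)
        u[0] = gamma
        u[-1] = off
        cp = np.empty_like(dg)
        dy = np.empty_like(dg)
        dz = np.empty_like(dg)
        np.divide(off, b[0], out=cp[0])
        np.divide(r[0], b[0], out=dy[0])
        np.divide(u[0], b[0], out=dz[0])
        scratch = np.empty_like(b[0])
        for j in range(1, n):
            np.multiply(cp[j - 1], off, out=scratch)
            np.subtract(b[j], scratch, out=scratch)  # denom
            np.divide(off, scratch, out=cp[j])
            dy[j] = (r[j] - off * dy[j - 1]) / scratch
            dz[j] = (u[j] - off * dz[j - 1]) / scratch
        y = dy
        z = dz
        for j in range(n - 2, -1, -1):
            y[j] -= cp[j] * y[j + 1]
            z[j] -= cp[j] * z[j + 1]
        # v = e_0 + (off/gamma) e_{n-1}
        vy = y[0] + (off / gamma) * y[-1]
        vz = z[0] + (off / gamma) * z[-1]
        y -= (vy / (1.0 + vz))[None, :] * z
        out[sl] = y.T
    return out


def _sample_window(rhat: np.ndarray, N: int, supersample: int, d: int):
    """Invert the spatial FFT per theta layer and sample integer pixels.

    ``rhat`` is (N, N//2+1, n_layers); returns the (2d+1, 2d+1, n_layers)
    window (axes dx, dy, theta) and the total mass on the coarse pixel grid.
    """
    side = 2 * d + 1
    n_layers = rhat.shape[2]
    win = (np.arange(-d, d + 1) * supersample) % N
    allpix = (np.arange(N // supersample) * supersample) % N
    values = np.empty((side, side, n_layers))
    mass_coarse = 0.0
    scale = float(supersample**2)
    for j in range(n_layers):
        spatial = scipy.fft.irfft2(rhat[:, :, j], s=(N, N)) * scale
        mass_coarse += float(spatial[np.ix_(allpix, allpix)].sum())
        # values[ix, iy, j]: rows of `spatial` are y, columns x
        values[:, :, j] = spatial[np.ix_(win, win)].T
    return values, mass_coarse


def _aggregate_theta(arr: np.ndarray, oversample: int) -> np.ndarray:
    """Box-sum ``oversample`` (odd) fine theta samples into each output bin.

    Output bin j collects fine bins o*j - (o-1)/2 .. o*j + (o-1)/2, i.e. the
    fine samples whose angle rounds to the bin center — the same binning the
    Monte-Carlo oracle applies to continuous angles.
    """
    if oversample == 1:
        return arr
    n_fine = arr.shape[-1]
    n_out = n_fine // oversample
    half = (oversample - 1) // 2
    rolled = np.roll(arr, half, axis=-1)
    return rolled.reshape(arr.shape[:-1] + (n_out, oversample)).sum(axis=-1)


def fp_resolvent_numeric(
    params: DirectionProcessParams,
    d: int = 65,
    n_theta: int = 16,
    pad_factor: int = 2,
    supersample: int = 4,
    theta_oversample: int = 3,
    renormalize: bool = True,
    neg_floor: float = -1e-8,
    auto_pad: bool = True,
    max_grid: int = 4096,
) -> ResolventKernel:
    """Solve the resolvent equation spectrally and crop to the kernel window.

    The equation is solved on a periodic domain at least ``pad_factor`` times
    larger than the (2d+1)^2 window, on a grid ``supersample`` times finer
    than one pixel, with ``theta_oversample * 2 * n_theta`` orientation
    samples box-aggregated to the 2*n_theta output bins (sub-bin orientations
    carry lateral drift that a coarse theta grid cannot represent). With
    ``auto_pad`` the domain is enlarged to cover ~6 mean path lengths
    (6/alpha) so that periodic wrap-around of long paths is negligible; the
    fine grid is capped at ``max_grid`` points per axis (a warning is logged
    when the cap bites). The Gaussian blur ``blur_s`` is applied in the
    Fourier domain before inversion. Total mass on the padded domain is 1 by
    construction; the mass cropped away is reported and, when ``renormalize``
    is set, restored by rescaling the cropped kernel.
    """
    if d < 1 or n_theta < 1 or pad_factor < 1 or supersample < 1:
        raise ValueError("grid parameters must be positive")
    if theta_oversample < 1 or theta_oversample % 2 == 0:
        raise ValueError("theta_oversample must be a positive odd integer")
    side = 2 * d + 1
    n_full = 2 * n_theta
    n_solve = n_full * theta_oversample
    dtheta_f = np.pi / (n_theta * theta_oversample)
    h = 1.0 / supersample
    pad_px = pad_factor * side
    if auto_pad:
        pad_px = max(pad_px, 2 * side + int(np.ceil(6.0 / params.alpha)))
    N = pad_px * supersample
    if N > max_grid:
        log.warning(
            "padded grid capped at %d points (wanted %d); wrap-around mass "
            "~exp(-%.2f) may contaminate the kernel at alpha=%g",
            max_grid,
            N,
            params.alpha * (max_grid / supersample - 2 * d),
            params.alpha,
        )
        N = max_grid
    dtype = np.complex64 if N * (N // 2 + 1) > 5e5 else np.complex128

    wy = 2 * np.pi * np.fft.fftfreq(N, d=h)       # axis 0 (rows = y)
    wx = 2 * np.pi * np.fft.rfftfreq(N, d=h)      # axis 1 (cols = x), reduced
    WY, WX = np.meshgrid(wy, wx, indexing="ij")
    wxf, wyf = WX.ravel(), WY.ravel()
    nf = wxf.size

    thetas = np.arange(n_solve) * dtheta_f
    cos_t, sin_t = np.cos(thetas), np.sin(thetas)
    dd = params.d33 / dtheta_f**2
    off = -dd
    rhs = np.zeros(n_solve, dtype=dtype)
    rhs[0] = params.alpha

    rhat = np.empty((nf, n_full), dtype=dtype)
    chunk = 1 << 16
    for lo in range(0, nf, chunk):
        sl = slice(lo, min(lo + chunk, nf))
        phase = wxf[sl, None] * cos_t[None, :] + wyf[sl, None] * sin_t[None, :]
        diag = ((params.alpha + 2.0 * dd) + 1j * phase).astype(dtype)
        sol = _solve_cyclic_tridiagonal(diag, off, rhs[None, :])
        rhat[sl] = _aggregate_theta(sol, theta_oversample)
    if not np.all(np.isfinite(rhat)):
        raise np.linalg.LinAlgError("resolvent system is numerically singular")

    blur = np.exp(-params.blur_s**2 * (wxf**2 + wyf**2) / 2.0)
    rhat *= blur[:, None].astype(dtype)
    mass_total = float(np.real(rhat[0].sum()))  # omega = 0 row

    rhat = rhat.reshape(N, wx.size, n_full)
    values, mass_coarse = _sample_window(rhat, N, supersample, d)
    minval = float(values.min())
    if minval < neg_floor:
        raise FloatingPointError(
            f"negative kernel entries ({minval:.3e}) signal discretization failure"
        )
    np.clip(values, 0.0, None, out=values)

    mass_window = float(values.sum())
    mass_cropped = float(mass_coarse - mass_window)
    if renormalize and mass_window > 0:
        values /= mass_window
    return ResolventKernel(
        values=values,
        d=d,
        n_theta=n_theta,
        params=params,
        mass_total=mass_total,
        mass_cropped=mass_cropped,
        renormalized=renormalize,
        min_value=minval,
    )


def fp_resolvent_series(
    alphas,
    d33: float,
    d: int = 65,
    n_theta: int = 16,
    blur_s: float = 0.5,
    pad_factor: int = 2,
    supersample: int = 2,
    theta_oversample: int = 3,
    dt: float = 0.5,
    absorb_every: int = 10,
    accumulate_every: int = 1,
    accumulate_warmup: float = 16.0,
    tail_tol: float = 1e-3,
    max_time: float = 4000.0,
    renormalize: bool = True,
) -> list[ResolventKernel]:
    """Resolvents for a whole batch of alphas from one time-domain evolution.

    The Green's function K_t is evolved with Strang splitting (transport is a
    per-frequency phase; the periodic second-difference theta-Laplacian is
    exponentiated exactly in the theta-Fourier basis, so the discrete
    operator matches :func:`fp_resolvent_numeric`). Mass leaving a sponge
    region near the periodic boundary is absorbed, so long paths neither wrap
    around nor require a domain proportional to 1/alpha; all resolvents
    R_alpha = alpha * Integral K_t exp(-alpha t) dt accumulate in one pass,
    stopped once every alpha's remaining tail is below ``tail_tol`` of its
    accumulated mass. K_t is sampled every step while t <=
    ``accumulate_warmup`` (the near-field of the kernel is built from small
    travel times and needs dt resolution) and every ``accumulate_every``
    steps afterwards; the exponential weight is integrated exactly over each
    sampling window, so the windows tile [0, inf) without gaps.

    The per-alpha cost is independent of 1/alpha, which makes this the engine
    of choice for grid fits with small decay rates.
    """
    alphas = np.atleast_1d(np.asarray(alphas, dtype=float))
    if np.any(alphas <= 0):
        raise ValueError("alphas must be > 0")
    if d33 < 0:
        raise ValueError("D33 must be >= 0")
    if theta_oversample < 1 or theta_oversample % 2 == 0:
        raise ValueError("theta_oversample must be a positive odd integer")
    side = 2 * d + 1
    n_solve = 2 * n_theta * theta_oversample
    dtheta_f = np.pi / (n_theta * theta_oversample)
    h = 1.0 / supersample
    P = pad_factor * side            # coarse extent in px
    N = P * supersample
    nr = N // 2 + 1

    wy = 2 * np.pi * np.fft.fftfreq(N, d=h)
    wx = 2 * np.pi * np.fft.rfftfreq(N, d=h)
    WY, WX = np.meshgrid(wy, wx, indexing="ij")
    wxf, wyf = WX.ravel(), WY.ravel()
    thetas = np.arange(n_solve) * dtheta_f
    phase_half = np.exp(
        -1j * (dt / 2.0) * (wxf[:, None] * np.cos(thetas) + wyf[:, None] * np.sin(thetas))
    ).astype(np.complex64)
    # exact exponential of the periodic second-difference Laplacian
    m = np.arange(n_solve)
    lam = -(2.0 - 2.0 * np.cos(m * 2 * np.pi / n_solve)) / dtheta_f**2
    diff_decay = np.exp(dt * d33 * lam).astype(np.complex64)

    # sponge: absorb everything within `margin` px of the periodic boundary
    margin = absorb_every * dt + 2.0
    coords = (np.arange(N) + N // 2) % N - N // 2
    sponge_1d = np.abs(coords * h) > (P / 2.0 - margin)
    sponge = sponge_1d[:, None] | sponge_1d[None, :]

    n_warm = int(np.ceil(accumulate_warmup / dt))

    def is_acc_step(s: int) -> bool:
        return s <= n_warm or (s - n_warm) % accumulate_every == 0

    def next_acc_step(s: int) -> int:
        s += 1
        while not is_acc_step(s):
            s += 1
        return s

    V = np.zeros((wxf.size, n_solve), dtype=np.complex64)
    V[:, 0] = 1.0  # K_0 = delta at the group identity
    # t = 0 contribution: weight window [0, dt/2]
    acc = [np.complex64(1.0 - np.exp(-a * dt / 2.0)) * V for a in alphas]
    prev_edge = dt / 2.0
    tmp = np.empty_like(V)

    t = 0.0
    step = 0
    survival = 1.0
    while t < max_time:
        # Strang splitting: half transport, full diffusion, half transport
        V *= phase_half
        Vf = scipy.fft.fft(V, axis=1)
        Vf *= diff_decay
        V = scipy.fft.ifft(Vf, axis=1)
        V *= phase_half
        t += dt
        step += 1
        if is_acc_step(step):
            next_edge = (t + next_acc_step(step) * dt) / 2.0
            for a, buf in zip(alphas, acc):
                w = np.exp(-a * prev_edge) - np.exp(-a * next_edge)
                np.multiply(V, np.complex64(w), out=tmp)
                buf += tmp
            prev_edge = next_edge
        if step % absorb_every == 0:
            Vg = V.reshape(N, nr, n_solve)
            for j in range(n_solve):
                sp = scipy.fft.irfft2(Vg[:, :, j], s=(N, N))
                sp[sponge] = 0.0
                Vg[:, :, j] = scipy.fft.rfft2(sp)
            survival = float(np.real(V[0, :].sum()))
            tails = survival * np.exp(-alphas * t)
            masses = np.array([float(np.real(b[0, :].sum())) for b in acc])
            if np.all(tails <= tail_tol * np.maximum(masses, 1e-12)):
                break

    blur = np.exp(-(blur_s**2) * (wxf**2 + wyf**2) / 2.0).astype(np.float32)
    kernels = []
    for a, buf in zip(alphas, acc):
        rhat = _aggregate_theta(buf, theta_oversample) * blur[:, None]
        mass_total = float(np.real(rhat[0].sum()))
        values, mass_coarse = _sample_window(
            rhat.reshape(N, nr, 2 * n_theta), N, supersample, d
        )
        np.clip(values, 0.0, None, out=values)
        mass_window = float(values.sum())
        if renormalize and mass_window > 0:
            values = values / mass_window
        kernels.append(
            ResolventKernel(
                values=values,
                d=d,
                n_theta=n_theta,
                params=DirectionProcessParams(alpha=float(a), d33=d33, blur_s=blur_s),
                mass_total=mass_total,
                mass_cropped=float(mass_coarse - mass_window),
                renormalized=renormalize,
            )
        )
    return kernels


def _simulate_endpoints(
    params: DirectionProcessParams,
    n_paths: int,
    dt: float,
    seed: int,
    chunk: int = 200_000,
):
    """Yield (x, y, theta) endpoint arrays of direction-process paths.

    Each path draws a lifetime T ~ Exp(alpha) and Euler-steps
    ``x += dt*cos(theta), y += dt*sin(theta), theta += sqrt(dt)*sigma*N(0,1)``
    until T (the last step is the remaining fraction of dt). Deterministic
    for a given seed.
    """
    sigma = params.sigma
    rng = np.random.default_rng(seed)
    for start in range(0, n_paths, chunk):
        m = min(chunk, n_paths - start)
        T = rng.exponential(1.0 / params.alpha, m)
        steps = np.floor(T / dt).astype(int)
        rem = T - steps * dt
        order = np.argsort(-steps, kind="stable")
        steps = steps[order]
        rem = rem[order]
        steps_asc = steps[::-1]
        x = np.zeros(m)
        y = np.zeros(m)
        th = np.zeros(m)
        outs = []
        ptr = m
        s = 0
        while ptr > 0:
            new_ptr = m - int(np.searchsorted(steps_asc, s, side="right"))
            if new_ptr < ptr:  # these paths end during this step
                sl = slice(new_ptr, ptr)
                r = rem[sl]
                outs.append(
                    (
                        x[sl] + r * np.cos(th[sl]),
                        y[sl] + r * np.sin(th[sl]),
                        th[sl].copy(),
                    )
                )
                ptr = new_ptr
                if ptr == 0:
                    break
            x[:ptr] += dt * np.cos(th[:ptr])
            y[:ptr] += dt * np.sin(th[:ptr])
            th[:ptr] += sigma * np.sqrt(dt) * rng.standard_normal(ptr)
            s += 1
        yield (
            np.concatenate([o[0] for o in outs]),
            np.concatenate([o[1] for o in outs]),
            np.concatenate([o[2] for o in outs]),
        )


def mc_resolvent(
    params: DirectionProcessParams,
    n_paths: int,
    dt: float = 0.1,
    seed: int = 0,
    d: int = 65,
    n_theta: int = 16,
    chunk: int = 200_000,
) -> ResolventKernel:
    """Monte-Carlo estimate of the resolvent by path simulation.

    Endpoints (see :func:`_simulate_endpoints`) are binned to the
    pixel/orientation grid; the histogram is normalized by the number of
    paths, so endpoints outside the window count toward the normalization but
    not the histogram. Deterministic for a given seed.
    """
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    side = 2 * d + 1
    n_full = 2 * n_theta
    dtheta = np.pi / n_theta
    hist = np.zeros(side * side * n_full)
    for x, y, th in _simulate_endpoints(params, n_paths, dt, seed, chunk):
        ix = np.rint(x).astype(int)
        iy = np.rint(y).astype(int)
        jt = np.mod(np.rint(th / dtheta).astype(int), n_full)
        ok = (np.abs(ix) <= d) & (np.abs(iy) <= d)
        if np.any(ok):
            flat = ((ix[ok] + d) * side + (iy[ok] + d)) * n_full + jt[ok]
            hist += np.bincount(flat, minlength=hist.size)

    values = hist.reshape(side, side, n_full) / n_paths
    return ResolventKernel(
        values=values,
        d=d,
        n_theta=n_theta,
        params=params,
        mass_total=1.0,
        mass_cropped=float(1.0 - values.sum()),
        renormalized=False,
    )


def mc_resolvent_blurred(
    params: DirectionProcessParams,
    n_paths: int,
    dt: float = 0.1,
    seed: int = 0,
    d: int = 65,
    n_theta: int = 16,
    bin_supersample: int = 4,
    chunk: int = 200_000,
) -> ResolventKernel:
    """Monte-Carlo oracle with the numeric kernel's Gaussian smoothing.

    Endpoints are histogrammed on a ``bin_supersample``-times finer spatial
    grid, convolved with a Gaussian of sigma ``params.blur_s`` (well sampled
    at the fine spacing), and the density is read off at the integer pixel
    positions — the same quantity :func:`fp_resolvent_numeric` computes, so
    the two can be compared bin for bin.
    """
    from scipy.ndimage import gaussian_filter

    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    ssb = bin_supersample
    margin = int(np.ceil(4 * params.blur_s)) + 1
    df = (d + margin) * ssb  # fine half-extent
    side_f = 2 * df + 1
    n_full = 2 * n_theta
    dtheta = np.pi / n_theta
    hist = np.zeros(side_f * side_f * n_full, dtype=np.float32)
    for x, y, th in _simulate_endpoints(params, n_paths, dt, seed, chunk):
        ix = np.rint(x * ssb).astype(int)
        iy = np.rint(y * ssb).astype(int)
        jt = np.mod(np.rint(th / dtheta).astype(int), n_full)
        ok = (np.abs(ix) <= df) & (np.abs(iy) <= df)
        if np.any(ok):
            flat = ((ix[ok] + df) * side_f + (iy[ok] + df)) * n_full + jt[ok]
            hist += np.bincount(flat, minlength=hist.size).astype(np.float32)
    fine = hist.reshape(side_f, side_f, n_full) / n_paths
    fine = gaussian_filter(fine, sigma=(params.blur_s * ssb, params.blur_s * ssb, 0))
    sel = (np.arange(-d, d + 1) + d + margin) * ssb
    values = fine[np.ix_(sel, sel)].astype(float) * ssb**2  # density at pixels
    return ResolventKernel(
        values=values,
        d=d,
        n_theta=n_theta,
        params=params,
        mass_total=1.0,
        mass_cropped=float(1.0 - values.sum()),
        renormalized=False,
    )


def symmetrize_projective(gamma: ResolventKernel) -> ProjectiveKernel:
    """Four-term forward/backward + pi-shift symmetrization (exact on bins).

    Using the time-reversal identity R(g^{-1}) = R(-x, -y, theta), the average
    of the kernel over {identity, group inversion, pi-shift, inverted
    pi-shift} equals the average over {identity, point reflection, pi bin
    roll, reflected roll}; all four maps are exact on the sampling grid and
    each preserves total mass.
    """
    vals = gamma.values
    if vals.shape[2] % 2 != 0:
        raise ValueError("theta bin count must be even for the pi-shift")
    n = vals.shape[2] // 2
    reflected = vals[::-1, ::-1, :]
    sym = 0.5 * (vals + reflected)
    out = 0.5 * (sym + np.roll(sym, -n, axis=2))
    return ProjectiveKernel(values=out, d=gamma.d, n_theta=gamma.n_theta, params=gamma.params)


def xy_marginal(kernel) -> np.ndarray:
    """Sum over the theta axis; mass is preserved."""
    vals = kernel.values if hasattr(kernel, "values") else np.asarray(kernel)
    return vals.sum(axis=2)


def projective_model_kernel(
    alpha: float,
    d33: float,
    d: int = 65,
    n_theta: int = 16,
    blur_s: float = 0.5,
    zero_origin: bool = False,
    **solver_kwargs,
) -> CooccurrenceKernel:
    """Normalized symmetrized direction-process kernel on the statistical grid.

    With ``zero_origin`` the spatial-origin voxel is cleared before
    normalization, mirroring the structural zero of statistical kernels (two
    distinct pixels never produce a (0, 0) offset).
    """
    params = DirectionProcessParams(alpha=alpha, d33=d33, blur_s=blur_s)
    gamma = fp_resolvent_numeric(
        params, d=d, n_theta=n_theta, renormalize=False, **solver_kwargs
    )
    folded = symmetrize_projective(gamma).fold()
    vals = folded.values
    if zero_origin:
        vals = vals.copy()
        vals[d, d, :] = 0.0
    total = vals.sum()
    if total <= 0:
        raise ValueError("model kernel has no mass on the window")
    return CooccurrenceKernel(vals / total, d=d, n_theta=n_theta, normalized=True)


def fit_kernel(
    k_stat: CooccurrenceKernel,
    alpha_grid,
    d33_grid,
    blur_s: float = 0.5,
    **series_kwargs,
) -> FitResult:
    """Least-squares grid search of (alpha, D33) against a statistical kernel.

    For every grid pair the symmetrized projective model kernel is built on
    ``k_stat``'s grid (with the spatial-origin voxel zeroed, since the
    statistical kernel is structurally zero there), normalized, and compared
    with the percent l2 metric. Model kernels come from the time-domain
    engine (:func:`fp_resolvent_series`), which shares one evolution per D33
    across the whole alpha grid. Ties break toward smaller alpha, then
    smaller D33 (row-major argmin).
    """
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    d33_grid = np.asarray(d33_grid, dtype=float)
    if alpha_grid.size == 0 or d33_grid.size == 0:
        raise ValueError("parameter grids must be nonempty")
    if not k_stat.normalized:
        raise ValueError("k_stat must be normalized")
    d = k_stat.d
    series_kwargs.setdefault("supersample", 2)
    series_kwargs.setdefault("dt", 0.75)
    surface = np.empty((alpha_grid.size, d33_grid.size))
    for j, dd in enumerate(d33_grid):
        series = fp_resolvent_series(
            alpha_grid,
            float(dd),
            d=d,
            n_theta=k_stat.n_theta,
            blur_s=blur_s,
            renormalize=False,
            **series_kwargs,
        )
        for i, gamma in enumerate(series):
            vals = symmetrize_projective(gamma).fold().values.copy()
            vals[d, d, :] = 0.0
            total = vals.sum()
            if total <= 0:
                surface[i, j] = np.inf
                continue
            surface[i, j] = kernel_distance(k_stat, vals / total)
    flat = int(np.argmin(surface))
    bi, bj = np.unravel_index(flat, surface.shape)
    return FitResult(
        best_alpha=float(alpha_grid[bi]),
        best_d33=float(d33_grid[bj]),
        error_percent=float(surface[bi, bj]),
        error_surface=surface,
        alpha_grid=alpha_grid,
        d33_grid=d33_grid,
    )


class DirectionProcessFit(BaseEstimator):
    """Estimator fitting direction-process parameters to a statistical kernel.

    Attributes (after fit): ``alpha_``, ``d33_``, ``error_percent_``,
    ``error_surface_``, ``kernel_`` (the best-fitting model kernel).
    """

    def __init__(self, alpha_grid=None, d33_grid=None, blur_s: float = 0.5):
        self.alpha_grid = alpha_grid
        self.d33_grid = d33_grid
        self.blur_s = blur_s

    def fit(self, X: CooccurrenceKernel, y=None):
        # paper-scale default endpoints; counts kept modest for desk use
        alpha_grid = (
            np.geomspace(1e-5, 1e-2, 50) if self.alpha_grid is None else self.alpha_grid
        )
        d33_grid = (
            np.geomspace(1e-6, 5e-3, 100) if self.d33_grid is None else self.d33_grid
        )
        res = fit_kernel(X, alpha_grid, d33_grid, blur_s=self.blur_s)
        self.alpha_ = res.best_alpha
        self.d33_ = res.best_d33
        self.error_percent_ = res.error_percent
        self.error_surface_ = res.error_surface
        self.result_ = res
        self.kernel_ = projective_model_kernel(
            res.best_alpha,
            res.best_d33,
            d=X.d,
            n_theta=X.n_theta,
            blur_s=self.blur_s,
            zero_origin=True,
        )
        return self
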