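"""Kernel containers, image I/O and pipeline configuration.

Kernels are stored in HDF5: one float64 dataset ``values`` plus metadata
attributes (``d``, ``n_theta``, ``kind``, ``normalized``, provenance and, for
model kernels, the direction-process parameters). Round trips are bit-exact
and the loader validates the array shape against the metadata.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
import json
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np

from .connectivity import DirectionProcessParams, ProjectiveKernel, ResolventKernel
from .cooc import CooccurrenceKernel

__all__ = [
    "PipelineConfig",
    "save_kernel",
    "load_kernel",
    "read_image",
    "read_mask",
    "write_label_map",
]


@dataclass
class PipelineConfig:
    """All pipeline defaults in one serializable document."""

    n_theta: int = 16
    d: int = 65
    sigma_int: float = 0.2
    wavelet_size: int = 51
    angular_order: int = 3
    nyquist_taper: float = 0.9
    blur_s: float = 0.5
    alpha_min: float = 1e-5
    alpha_max: float = 1e-2
    alpha_count: int = 50
    d33_min: float = 1e-6
    d33_max: float = 5e-3
    d33_count: int = 100
    max_groups: int = 10
    min_group_size: int = 10
    background_scale: float = 15.0
    seed: int = 0

    def alpha_grid(self) -> np.ndarray:
        return np.geomspace(self.alpha_min, self.alpha_max, self.alpha_count)

    def d33_grid(self) -> np.ndarray:
        return np.geomspace(self.d33_min, self.d33_max, self.d33_count)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


def save_kernel(kernel, path, provenance: str = "") -> None:
    """Write a co-occurrence / resolvent / projective kernel to HDF5."""
    if isinstance(kernel, CooccurrenceKernel):
        kind, extra = "cooc", {"normalized": bool(kernel.normalized)}
    elif isinstance(kernel, ResolventKernel):
        kind = "resolvent"
        extra = {
            "alpha": kernel.params.alpha,
            "d33": kernel.params.d33,
            "blur_s": kernel.params.blur_s,
            "mass_total": kernel.mass_total,
            "mass_cropped": kernel.mass_cropped,
            "normalized": bool(kernel.renormalized),
        }
    elif isinstance(kernel, ProjectiveKernel):
        kind = "projective"
        extra = {}
        if kernel.params is not None:
            extra.update(
                alpha=kernel.params.alpha,
                d33=kernel.params.d33,
                blur_s=kernel.params.blur_s,
            )
    else:
        raise TypeError(f"cannot save kernel of type {type(kernel).__name__}")
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=np.asarray(kernel.values, dtype=np.float64))
        f.attrs["kind"] = kind
        f.attrs["d"] = int(kernel.d)
        f.attrs["n_theta"] = int(kernel.n_theta)
        f.attrs["provenance"] = provenance
        for key, val in extra.items():
            f.attrs[key] = val


def load_kernel(path):
    """Load a kernel container, validating shape against metadata."""
    with h5py.File(path, "r") as f:
        values = f["values"][()]
        kind = f.attrs["kind"]
        d = int(f.attrs["d"])
        n_theta = int(f.attrs["n_theta"])
        side = 2 * d + 1
        layers = n_theta if kind == "cooc" else 2 * n_theta
        if values.shape != (side, side, layers):
            raise ValueError(
                f"kernel shape {values.shape} does not match metadata "
                f"(expected {(side, side, layers)})"
            )
        if kind == "cooc":
            return CooccurrenceKernel(
                values, d=d, n_theta=n_theta, normalized=bool(f.attrs["normalized"])
            )
        params = None
        if "alpha" in f.attrs:
            params = DirectionProcessParams(
                alpha=float(f.attrs["alpha"]),
                d33=float(f.attrs["d33"]),
                blur_s=float(f.attrs.get("blur_s", 0.5)),
            )
        if kind == "resolvent":
            return ResolventKernel(
                values,
                d=d,
                n_theta=n_theta,
                params=params,
                mass_total=float(f.attrs.get("mass_total", 1.0)),
                mass_cropped=float(f.attrs.get("mass_cropped", 0.0)),
                renormalized=bool(f.attrs.get("normalized", False)),
            )
        if kind == "projective":
            return ProjectiveKernel(values, d=d, n_theta=n_theta, params=params)
        raise ValueError(f"unknown kernel kind {kind!r}")


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF image as float in [0, 1].

    RGB images use the green channel (the highest-contrast channel for
    retinal fundus photographs); integer dtypes are rescaled by their range.
    """
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 1]
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
    return arr


def read_mask(path) -> np.ndarray:
    """Read a binary mask image (any nonzero value is foreground)."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr.max(axis=2)
    return (arr > 0).astype(np.uint8)


def write_label_map(path, label_map: np.ndarray) -> None:
    """Write a label map as 16-bit PNG (0 = background/pruned)."""
    iio.imwrite(path, (label_map + 1).astype(np.uint16))
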