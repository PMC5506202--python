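"""Optional full-dataset reproduction workflow.

Consumes a user-supplied retinal dataset (images + vessel ground truth +
optional artery/vein labels, matching filenames across directories), learns
the whole-vasculature and AV-separated statistical kernels, writes the
pairwise kernel-distance table and the best direction-process fits.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cooc import (
    LineCooccurrence,
    build_interest_points,
    kernel_distance,
    thin_to_centerlines,
)
from .connectivity import fit_kernel
from .kio import read_image, read_mask, save_kernel
from .oscore import dominant_orientations, make_cake_wavelets, orientation_score

log = logging.getLogger(__name__)


def _parse_grid(spec: str) -> np.ndarray:
    lo, hi, n = spec.split(",")
    return np.geomspace(float(lo), float(hi), int(n))


def run_reproduction(
    image_dir,
    vessel_dir,
    av_dir=None,
    n_theta: int = 16,
    d: int = 65,
    wavelet_size: int = 51,
    alpha_grid="1e-5,1e-2,20",
    d33_grid="1e-6,5e-3,20",
    out_dir="reproduction",
):
    """Learn kernels from a dataset directory, compare and fit them.

    Returns a dict with the learned kernels, the pairwise comparison table
    and the per-kernel fit results; artifacts are written under ``out_dir``.
    """
    image_dir, vessel_dir = Path(image_dir), Path(vessel_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vessel_paths = sorted(p for p in vessel_dir.iterdir() if p.is_file())
    if not vessel_paths:
        raise FileNotFoundError(f"no vessel ground-truth files in {vessel_dir}")
    missing = [p.name for p in vessel_paths if not (image_dir / p.name).exists()]
    if missing:
        raise FileNotFoundError(f"missing images for ground truth: {missing}")

    whole_samples, av_samples = [], []
    for vessel_path in vessel_paths:
        image = read_image(image_dir / vessel_path.name)
        centerlines = thin_to_centerlines(read_mask(vessel_path))
        size = min(wavelet_size, min(image.shape))
        size -= 1 - size % 2
        wavelets = make_cake_wavelets(n_theta, size)
        omap = dominant_orientations(
            orientation_score(image, wavelets), centerlines.astype(bool)
        )
        whole_samples.append(build_interest_points(centerlines, omap))
        if av_dir is not None:
            av = read_image(Path(av_dir) / vessel_path.name)
            artery = centerlines * (av > 0.5)
            vein = centerlines * (av <= 0.5)
            av_samples.append(
                (build_interest_points(artery, omap), build_interest_points(vein, omap))
            )

    kernels = {"whole": LineCooccurrence(d=d, n_theta=n_theta).fit(whole_samples).kernel_}
    if av_samples:
        kernels["av"] = LineCooccurrence(d=d, n_theta=n_theta).fit(av_samples).kernel_
    for name, kern in kernels.items():
        save_kernel(kern, out / f"kernel_{name}.h5", provenance=f"reproduce {name}")

    names = list(kernels)
    rows = [
        {"k1": a, "k2": b, "error_percent": kernel_distance(kernels[a], kernels[b])}
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    ]
    table = pd.DataFrame(rows, columns=["k1", "k2", "error_percent"])
    table.to_csv(out / "pairwise_errors.csv", index=False)

    alphas = _parse_grid(alpha_grid) if isinstance(alpha_grid, str) else np.asarray(alpha_grid)
    d33s = _parse_grid(d33_grid) if isinstance(d33_grid, str) else np.asarray(d33_grid)
    fits = {}
    fit_rows = []
    for name, kern in kernels.items():
        res = fit_kernel(kern, alphas, d33s)
        fits[name] = res
        fit_rows.append(
            {
                "kernel": name,
                "error_percent": res.error_percent,
                "alpha": res.best_alpha,
                "d33": res.best_d33,
                "sigma": float(np.sqrt(2 * res.best_d33)),
            }
        )
        log.info(
            "fit %s: alpha=%.5g d33=%.5g error=%.4f%%",
            name,
            res.best_alpha,
            res.best_d33,
            res.error_percent,
        )
    pd.DataFrame(fit_rows).to_csv(out / "best_fits.csv", index=False)
    return {"kernels": kernels, "pairwise": table, "fits": fits}
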