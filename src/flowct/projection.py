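"""Linear forward-projection observation model and the noise model.

A projection is the mean of the voxels along one body axis — the linear
operator emulating a digitally reconstructed radiograph:

    coronal:  y(h, w, c) = (1/D) * sum_d x(d, h, w, c)
    sagittal: y(h, d, c) = (1/W) * sum_w x(d, h, w, c)

The ultra-low-dose protocol is emulated by adding i.i.d. Gaussian noise
N(0, sigma^2) per pixel on the 8-bit (0-255) intensity scale; the
reference ultra-low-dose setting is sigma^2 = 100.  No attenuation
physics (Beer-Lambert, scatter, cone-beam geometry) is modeled.
"""

from __future__ import annotations

import numpy as np

from .io_preprocess import Projection, Volume8
from .tape import Tensor, as_tensor

__all__ = ["VIEWS", "project", "project_array", "project_multi", "add_noise"]

#: view label -> axis of the (D, H, W, C) grid that is averaged out
VIEWS = {"coronal": 0, "sagittal": 2}


def project_array(x, view: str):
    """Axis-mean projection of a (D,H,W,C) or (B,D,H,W,C) array/Tensor.

    Works on plain arrays and on :class:`~flowct.tape.Tensor` (so the MAP
    objective can differentiate through it).  Coronal output is (H, W, C);
    sagittal output is (H, D, C) — the averaged-out width axis is replaced
    by depth as the image width.
    """
    if view not in VIEWS:
        raise ValueError(f"unknown view {view!r}; expected one of {sorted(VIEWS)}")
    is_tensor = isinstance(x, Tensor)
    t = as_tensor(x)
    batched = t.ndim == 5
    axis = VIEWS[view] + (1 if batched else 0)
    y = t.mean(axis=axis)
    if view == "sagittal":
        # (B?, D, H, C) -> (B?, H, D, C)
        y = y.transpose((0, 2, 1, 3) if batched else (1, 0, 2))
    return y if is_tensor else y.data


def project(vol: Volume8, view: str) -> Projection:
    """Project a volume onto one view plane, keeping its intensity scale."""
    return Projection(project_array(vol.voxels, view), view=view, noise_sigma=0.0)


def project_multi(vol: Volume8, views) -> list:
    """Project onto several distinct views."""
    views = list(views)
    if not views:
        raise ValueError("need at least one view")
    if len(set(views)) != len(views):
        raise ValueError(f"duplicate views in {views}")
    return [project(vol, v) for v in views]


def add_noise(y: Projection, sigma: float, seed: int | None = None) -> Projection:
    """Add i.i.d. N(0, sigma^2) pixel noise (sigma on the 8-bit scale)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return Projection(y.pixels.copy(), view=y.view, noise_sigma=0.0, seed=seed)
    rng = np.random.default_rng(seed)
    noisy = y.pixels + rng.normal(0.0, sigma, size=y.pixels.shape)
    return Projection(noisy, view=y.view, noise_sigma=float(sigma), seed=seed)
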