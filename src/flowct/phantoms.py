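"""Synthetic chest-like phantom volumes and dataset splits.

The generator composes simple geometric structures with CT-like intensity
contrast on the 0-255 scale: an elliptical body (soft tissue), two
low-intensity lung ellipsoids, a bright heart sphere, a spine cylinder
(bone) and a flat scanner-bed slab near the posterior face.  Per-subject
jitter of positions, sizes and intensities gives the population nontrivial
variance while keeping a shared anatomy-like structure, so a generative
prior is learnable from a few dozen subjects.  A light Gaussian blur makes
the intensity variation smooth.

These phantoms emulate a chest-CT cohort only in the weak sense a
flow-based prior needs (a learnable image distribution); they carry no
attenuation physics or pathology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_preprocess import Volume8

__all__ = ["PhantomSpec", "generate_phantom", "sample_structures", "make_dataset"]

#: default split ratios emulate a 450-subject cohort divided 384/32/34
DEFAULT_SPLIT_RATIOS = (384 / 450, 32 / 450, 34 / 450)


@dataclass
class PhantomSpec:
    """Geometry and jitter ranges for the phantom population.

    All positions and semi-axes are fractions of the grid dimensions;
    intensities are 0-255 gray levels.  ``jitter`` scales the per-subject
    random perturbations (0 disables them).
    """

    shape: tuple = (32, 32, 32)
    body_axes: tuple = (0.36, 0.42, 0.44)
    body_intensity: float = 120.0
    lung_axes: tuple = (0.16, 0.30, 0.15)
    lung_centers: tuple = ((0.50, 0.48, 0.28), (0.50, 0.48, 0.72))
    lung_intensity: float = 35.0
    heart_center: tuple = (0.58, 0.55, 0.54)
    heart_radius: float = 0.13
    heart_intensity: float = 140.0
    spine_center: tuple = (0.78, 0.50)  # (depth, width), cylinder along height
    spine_radius: float = 0.06
    spine_intensity: float = 220.0
    bed_depth: float = 0.93  # slab position as depth fraction
    bed_thickness: float = 0.05
    bed_intensity: float = 80.0
    background: float = 0.0
    smooth_sigma: float = 0.7  # voxels
    jitter: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if any(s < 4 for s in self.shape):
            raise ValueError("grid too small for the phantom structures")
        for val in (self.body_intensity, self.lung_intensity, self.heart_intensity,
                    self.spine_intensity, self.bed_intensity, self.background):
            if not 0.0 <= val <= 255.0:
                raise ValueError("intensities must lie in [0, 255]")


def _rng_for(spec: PhantomSpec, subject_index: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, int(subject_index)])


def sample_structures(spec: PhantomSpec, subject_index: int) -> dict:
    """Draw the jittered structure parameters for one subject.

    Returns absolute voxel coordinates/semi-axes.  Exposed separately so the
    voxelization can be cross-checked against an independent evaluation of
    the same geometry.
    """
    rng = _rng_for(spec, subject_index)
    j = spec.jitter
    d, h, w = spec.shape

    def pos(frac, dim):
        return (frac + j * rng.uniform(-0.03, 0.03)) * dim

    def ax(frac, dim):
        return max(1.0, (frac * (1.0 + j * rng.uniform(-0.10, 0.10))) * dim)

    def inten(base):
        return float(np.clip(base + j * rng.uniform(-10, 10), 0, 255))

    st = {
        "body": {"center": (pos(0.5, d), pos(0.5, h), pos(0.5, w)),
                 "axes": tuple(ax(a, s) for a, s in zip(spec.body_axes, (d, h, w))),
                 "intensity": inten(spec.body_intensity)},
        "lungs": [], "shape": (d, h, w),
    }
    for c in spec.lung_centers:
        st["lungs"].append({
            "center": (pos(c[0], d), pos(c[1], h), pos(c[2], w)),
            "axes": tuple(ax(a, s) for a, s in zip(spec.lung_axes, (d, h, w))),
            "intensity": inten(spec.lung_intensity)})
    st["heart"] = {"center": (pos(spec.heart_center[0], d),
                              pos(spec.heart_center[1], h),
                              pos(spec.heart_center[2], w)),
                   "radius": ax(spec.heart_radius, min(d, h, w)),
                   "intensity": inten(spec.heart_intensity)}
    st["spine"] = {"center": (pos(spec.spine_center[0], d), pos(spec.spine_center[1], w)),
                   "radius": ax(spec.spine_radius, min(d, w)),
                   "intensity": inten(spec.spine_intensity)}
    st["bed"] = {"depth": pos(spec.bed_depth, d),
                 "thickness": max(1.0, spec.bed_thickness * d),
                 "intensity": inten(spec.bed_intensity)}
    return st


def _ellipsoid_mask(shape, center, axes) -> np.ndarray:
    d, h, w = shape
    zz, yy, xx = np.ogrid[:d, :h, :w]
    return (((zz - center[0]) / axes[0]) ** 2
            + ((yy - center[1]) / axes[1]) ** 2
            + ((xx - center[2]) / axes[2]) ** 2) <= 1.0


def generate_phantom(spec: PhantomSpec, subject_index: int = 0) -> Volume8:
    """Voxelize one subject; deterministic given (spec.seed, subject_index)."""
    st = sample_structures(spec, subject_index)
    d, h, w = spec.shape
    for key in ("body",):
        c, a = st[key]["center"], st[key]["axes"]
        if any(ci - ai < -0.5 or ci + ai > dim + 0.5
               for ci, ai, dim in zip(c, a, (d, h, w))):
            raise ValueError(f"{key} structure exceeds the grid")

    vol = np.full((d, h, w), spec.background, dtype=np.float64)
    body = _ellipsoid_mask((d, h, w), st["body"]["center"], st["body"]["axes"])
    vol[body] = st["body"]["intensity"]
    for lung in st["lungs"]:
        vol[_ellipsoid_mask((d, h, w), lung["center"], lung["axes"]) & body] = lung["intensity"]
    hc = st["heart"]
    vol[_ellipsoid_mask((d, h, w), hc["center"], (hc["radius"],) * 3) & body] = hc["intensity"]
    sp = st["spine"]
    zz, _, xx = np.ogrid[:d, :h, :w]
    spine = ((zz - sp["center"][0]) ** 2 + (xx - sp["center"][1]) ** 2) <= sp["radius"] ** 2
    vol[np.broadcast_to(spine, (d, h, w)) & body] = sp["intensity"]
    bed = st["bed"]
    d0 = int(round(bed["depth"]))
    d1 = min(d, d0 + int(round(bed["thickness"])))
    vol[d0:d1, :, :] = np.maximum(vol[d0:d1, :, :], bed["intensity"])

    if spec.smooth_sigma > 0:
        vol = gaussian_filter(vol, sigma=spec.smooth_sigma, mode="nearest")
    return Volume8(np.clip(vol, 0.0, 255.0), scale_tag="eightbit", bits=8)


def make_dataset(n_subjects: int, split_ratios=DEFAULT_SPLIT_RATIOS, seed: int = 0) -> dict:
    """Randomly split subject indices into train/val/test.

    Sizes follow largest-remainder rounding of the ratios (so 450 subjects
    at the default ratios give 384/32/34).  Splits are disjoint and cover
    all subjects; every split must be nonempty.
    """
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    ratios = np.asarray(split_ratios, dtype=np.float64)
    if abs(ratios.sum() - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    quotas = ratios * n_subjects
    sizes = np.floor(quotas).astype(int)
    remainder = int(n_subjects - sizes.sum())
    order = np.argsort(-(quotas - sizes), kind="stable")
    for i in range(remainder):
        sizes[order[i]] += 1
    if (sizes == 0).any():
        raise ValueError(f"empty split for n={n_subjects}, ratios={tuple(ratios)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_subjects)
    train = sorted(int(i) for i in perm[:sizes[0]])
    val = sorted(int(i) for i in perm[sizes[0]:sizes[0] + sizes[1]])
    test = sorted(int(i) for i in perm[sizes[0] + sizes[1]:])
    return {"train": train, "val": val, "test": test}
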