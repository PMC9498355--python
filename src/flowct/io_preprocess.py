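"""Volume / projection I/O and intensity-scale conventions.

The whole pipeline works on three intensity scales:

* **HU** — calibrated CT numbers (air = -1000), carried by :class:`VolumeHU`.
* **eightbit** — the gradation-reduced 0-255 scale produced by
  :func:`reduce_gradation`; the quantized k-bit stages of progressive
  training also live here (integer levels 0..2^k-1 stored in float).
* **unit** — the [0, 1) model space the flow consumes, produced by
  :func:`to_model_space`.

Gradation reduction maps HU to 0-255 by clipping at -1000 below and the
volume maximum above, then rescaling linearly so that -1000 HU -> 0 and
max -> 255.  Values stay floating point until an explicit k-bit
quantization (floor-division binning), which avoids double rounding across
the progressive-training stages.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import imageio.v3 as iio
import nibabel as nib
import numpy as np

__all__ = [
    "VolumeHU", "Volume8", "Projection",
    "reduce_gradation", "quantize_bits", "to_model_space", "from_model_space",
    "downsample", "read_volume", "write_volume",
    "read_projection", "write_projection",
]

#: axes are ordered (depth = anterior-posterior, height = cranio-caudal,
#: width = left-right), 0-based.


@dataclass
class VolumeHU:
    """Raw 3D scan in Hounsfield units, shape (D, H, W)."""

    voxels: np.ndarray
    spacing: tuple | None = None  # mm per axis, optional metadata

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"VolumeHU expects a rank-3 grid, got {self.voxels.ndim}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("VolumeHU voxels must be finite")


@dataclass
class Volume8:
    """Gradation-reduced volume, shape (D, H, W, C), C=1 by default.

    ``scale_tag`` is ``"eightbit"`` (values in [0, 255]) or ``"unit"``
    (values in [0, 1]); ``bits`` is the effective gradation (1-8).
    """

    voxels: np.ndarray
    scale_tag: str = "eightbit"
    bits: int = 8

    def __post_init__(self):
        v = np.asarray(self.voxels, dtype=np.float64)
        if v.ndim == 3:
            v = v[..., None]
        if v.ndim != 4:
            raise ValueError(f"Volume8 expects rank 3 or 4, got {v.ndim}")
        if self.scale_tag not in ("eightbit", "unit"):
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        if not 1 <= self.bits <= 8:
            raise ValueError(f"bits must be in 1..8, got {self.bits}")
        hi = 255.0 if self.scale_tag == "eightbit" else 1.0
        if v.size and (v.min() < -1e-9 or v.max() > hi + 1e-9):
            raise ValueError(f"values outside the declared {self.scale_tag} range")
        self.voxels = v

    @property
    def shape(self):
        return self.voxels.shape

    def to_unit(self) -> "Volume8":
        """Exact rescale eightbit -> unit (multiplication by 1/255)."""
        if self.scale_tag == "unit":
            return self
        return Volume8(self.voxels / 255.0, scale_tag="unit", bits=self.bits)

    def to_eightbit(self) -> "Volume8":
        if self.scale_tag == "eightbit":
            return self
        return Volume8(self.voxels * 255.0, scale_tag="eightbit", bits=self.bits)


@dataclass
class Projection:
    """A 2D view of a volume, shape (H2D, W2D, C)."""

    pixels: np.ndarray
    view: str = "coronal"
    noise_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        p = np.asarray(self.pixels, dtype=np.float64)
        if p.ndim == 2:
            p = p[..., None]
        if p.ndim != 3:
            raise ValueError(f"Projection expects rank 2 or 3 pixels, got {p.ndim}")
        self.pixels = p


# ---------------------------------------------------------------------------
# intensity transforms
# ---------------------------------------------------------------------------

def reduce_gradation(src: VolumeHU) -> Volume8:
    """Reduce a HU volume to the 0-255 scale.

    out = 255 * (clip(src, -1000, max(src)) + 1000) / (max(src) + 1000)

    The lower clip endpoint (-1000 HU, air) maps exactly to 0 and the volume
    maximum maps exactly to 255.  Output stays floating point.
    """
    v = src.voxels
    vmax = float(v.max())
    if vmax <= -1000.0:
        raise ValueError("cannot reduce gradation: max(src) <= -1000 HU")
    out = 255.0 * (np.clip(v, -1000.0, vmax) + 1000.0) / (vmax + 1000.0)
    return Volume8(out, scale_tag="eightbit", bits=8)


def quantize_bits(vol: Volume8, k: int) -> Volume8:
    """Quantize an eightbit volume to k-bit gradation: v -> floor(v / 2^(8-k)).

    Output values are the integer levels 0 .. 2^k - 1 (stored as float),
    with ``bits`` set to k.
    """
    if vol.scale_tag != "eightbit":
        raise ValueError("quantize_bits expects an eightbit volume")
    if not (isinstance(k, (int, np.integer)) and 1 <= k <= 8):
        raise ValueError(f"bit depth k must be an integer in 1..8, got {k}")
    step = 2.0 ** (8 - k)
    levels = np.floor(vol.voxels / step)
    np.clip(levels, 0, 2 ** k - 1, out=levels)  # guard v == 255 exactly at k=8
    out = Volume8.__new__(Volume8)  # bypass range check: levels are 0..2^k-1
    out.voxels = levels
    out.scale_tag = "eightbit"
    out.bits = k
    return out


def to_model_space(vol: Volume8, dequantize: bool = False, seed: int | None = None) -> Volume8:
    """Map k-bit integer levels to the model's [0, 1) space.

    ``(v + u) / 2^k`` with u ~ Uniform[0,1) when dequantizing (training),
    else ``(v + 0.5) / 2^k`` (deterministic bin centers, used when
    evaluating likelihoods during reconstruction).
    """
    k = vol.bits
    if dequantize:
        rng = np.random.default_rng(seed)
        u = rng.random(vol.voxels.shape)
    else:
        u = 0.5
    return Volume8((vol.voxels + u) / 2.0 ** k, scale_tag="unit", bits=k)


def from_model_space(x: np.ndarray, bits: int = 8) -> Volume8:
    """Clip a model-space array back into a unit-scale Volume8."""
    return Volume8(np.clip(x, 0.0, 1.0), scale_tag="unit", bits=bits)


def downsample(vol: Volume8, factor: int) -> Volume8:
    """Mean-pool each spatial axis by an integer factor."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    d, h, w, c = vol.shape
    if any(s % factor for s in (d, h, w)):
        raise ValueError(f"shape {vol.shape[:3]} not divisible by factor {factor}")
    v = vol.voxels.reshape(d // factor, factor, h // factor, factor,
                           w // factor, factor, c)
    return Volume8(v.mean(axis=(1, 3, 5)), scale_tag=vol.scale_tag, bits=vol.bits)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_NIFTI_EXT = (".nii", ".nii.gz")
_PROJ_EXT = (".png", ".tif", ".tiff")


def _is_nifti(path: str) -> bool:
    return path.endswith(".nii") or path.endswith(".nii.gz")


def write_volume(vol, path: str) -> None:
    """Write a VolumeHU or Volume8 as NIfTI.

    The scale tag and bit depth of a Volume8 are recorded in the NIfTI
    ``descrip`` header field so reads round-trip the type.
    """
    if not _is_nifti(path):
        raise IOError(f"unsupported volume extension for {path!r} (use .nii/.nii.gz)")
    if isinstance(vol, Volume8):
        data = vol.voxels
        descrip = f"flowct:scale={vol.scale_tag};bits={vol.bits}"
    elif isinstance(vol, VolumeHU):
        data = vol.voxels
        descrip = "flowct:scale=hu"
    else:
        raise TypeError(f"cannot write object of type {type(vol).__name__}")
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine=np.eye(4))
    img.header["descrip"] = descrip.encode()
    nib.save(img, path)


def read_volume(path: str):
    """Read a NIfTI volume, returning VolumeHU or Volume8 per its header tag."""
    if not os.path.exists(path):
        raise IOError(f"volume file not found: {path!r}")
    if not _is_nifti(path):
        raise IOError(f"unsupported volume extension for {path!r} (use .nii/.nii.gz)")
    try:
        img = nib.load(path)
        data = np.asarray(img.dataobj, dtype=np.float64)
        descrip = bytes(img.header["descrip"].tobytes()).rstrip(b"\x00").decode(errors="replace")
    except Exception as exc:  # corrupt file
        raise IOError(f"failed to read volume {path!r}: {exc}") from exc
    tags = {}
    if descrip.startswith("flowct:"):
        for kv in descrip[len("flowct:"):].split(";"):
            if "=" in kv:
                key, val = kv.split("=", 1)
                tags[key] = val
    if tags.get("scale") in ("eightbit", "unit"):
        return Volume8(data, scale_tag=tags["scale"], bits=int(tags.get("bits", 8)))
    return VolumeHU(data.reshape(data.shape[:3]))


_PNG_SCALE = 65535.0 / 255.0  # integer gray levels round-trip exactly


def write_projection(p: Projection, path: str) -> None:
    """Write a projection image.

    ``.png`` stores 16-bit with a fixed 0-255 -> 0-65535 mapping (exact for
    integer gray levels; values outside [0, 255] are clipped).  ``.tif``
    stores float32 and preserves negative / out-of-range values, which noisy
    projections can have.  A sidecar ``<path>.meta.txt`` records view, sigma
    and seed.
    """
    ext = os.path.splitext(path)[1].lower()
    pix = p.pixels[..., 0] if p.pixels.shape[-1] == 1 else p.pixels
    if ext == ".png":
        arr = np.clip(np.round(pix * _PNG_SCALE), 0, 65535).astype(np.uint16)
        iio.imwrite(path, arr)
    elif ext in (".tif", ".tiff"):
        iio.imwrite(path, pix.astype(np.float32))
    else:
        raise IOError(f"unsupported projection extension for {path!r} (use .png/.tif)")
    with open(path + ".meta.txt", "w") as fh:
        fh.write(f"view={p.view}\nsigma={p.noise_sigma}\nseed={p.seed}\n")


def read_projection(path: str) -> Projection:
    if not os.path.exists(path):
        raise IOError(f"projection file not found: {path!r}")
    ext = os.path.splitext(path)[1].lower()
    if ext not in _PROJ_EXT:
        raise IOError(f"unsupported projection extension for {path!r} (use .png/.tif)")
    try:
        arr = np.asarray(iio.imread(path))
    except Exception as exc:
        raise IOError(f"failed to read projection {path!r}: {exc}") from exc
    if ext == ".png":
        pix = arr.astype(np.float64) / _PNG_SCALE
    else:
        pix = arr.astype(np.float64)
    meta = {"view": "coronal", "sigma": "0.0", "seed": "None"}
    meta_path = path + ".meta.txt"
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            for line in fh:
                if "=" in line:
                    key, val = line.strip().split("=", 1)
                    meta[key] = val
    seed = None if meta["seed"] in ("None", "") else int(meta["seed"])
    return Projection(pix, view=meta["view"], noise_sigma=float(meta["sigma"]), seed=seed)
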