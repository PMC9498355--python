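"""Multi-scale invertible 3D flow with exact log-likelihood (3D GLOW).

Architecture: K levels, each a 3D squeeze (spatial factors folded into
channels) followed by `depth` flow steps (actnorm -> invertible 1x1x1
convolution -> affine coupling); every level but the last factors out half
its channels through a learned conditional Gaussian ("split"), and the
final latent carries a learned unconditional Gaussian top prior
(mean mu_theta, diagonal scale Sigma_theta).

The affine-coupling scale uses the stabilized form

    scale = sigmoid(raw + 2.0) + eps,   eps = 1e-3,

which is bounded in (eps, 1 + eps) so no division by zero can occur in the
inverse pass; at zero initialization the scale is sigmoid(2) + eps ~ 0.8818
rather than 1.

The model gives, per sample, log p(x) = sum_k log p(z_k) + log|det dz/dx|.
Everything is built on :mod:`flowct.tape`, so the same code path provides
gradients with respect to parameters (training) or latents (MAP
reconstruction through the decoder).
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, asdict

import numpy as np
import scipy.linalg
from scipy.special import expit

from .tape import Tensor, as_tensor, concat, conv3d, matmul_last

__all__ = ["FlowConfig", "Glow3D", "coupling_scale"]

_LOG2PI = float(np.log(2.0 * np.pi))


def coupling_scale(raw, eps: float = 1e-3):
    """Stabilized affine-coupling scale: sigmoid(raw + 2.0) + eps.

    Bounded in (eps, 1 + eps); saturates to eps as raw -> -inf and to
    1 + eps as raw -> +inf.  Accepts arrays or scalars.
    """
    return expit(np.asarray(raw, dtype=np.float64) + 2.0) + eps


@dataclass
class FlowConfig:
    """Hyperparameters of the flow.

    The reference full-scale setting is input 128^3, 5 levels, depth 8,
    width 512; the desk-scale default used throughout the tests is far
    smaller.  Each spatial dim must be divisible by its squeeze factor
    raised to the number of levels.
    """

    shape: tuple = (32, 32, 32, 1)  # (D, H, W, C)
    levels: int = 3
    depth: int = 4
    width: int = 64
    eps: float = 1e-3
    learn_top: bool = True
    squeeze_factor: tuple = (2, 2, 2)
    permutation: str = "inv1x1"  # "inv1x1" | "identity"
    identity_init: bool = False
    seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        self.squeeze_factor = tuple(int(f) for f in self.squeeze_factor)
        if len(self.shape) != 4:
            raise ValueError("shape must be (D, H, W, C)")
        if self.depth < 1 or self.levels < 1:
            raise ValueError("levels and depth must be >= 1")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.permutation not in ("inv1x1", "identity"):
            raise ValueError(f"unknown permutation {self.permutation!r}")
        d, h, w, _ = self.shape
        fd, fh, fw = self.squeeze_factor
        for dim, f in ((d, fd), (h, fh), (w, fw)):
            if dim % (f ** self.levels):
                raise ValueError(
                    f"spatial dim {dim} not divisible by {f}^{self.levels}")


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def _spatial(x) -> int:
    return int(np.prod(x.shape[1:4]))


class _ActNorm:
    """Per-channel affine y = (x + bias) * exp(logs), data-dependent init."""

    def __init__(self, n_channels: int, identity_init: bool):
        self.bias = Tensor(np.zeros(n_channels), requires_grad=True)
        self.logs = Tensor(np.zeros(n_channels), requires_grad=True)
        self.initialized = bool(identity_init)

    def maybe_init(self, x_data: np.ndarray) -> None:
        if self.initialized:
            return
        mean = x_data.mean(axis=(0, 1, 2, 3))
        std = x_data.std(axis=(0, 1, 2, 3))
        self.bias.data = -mean
        self.logs.data = -np.log(std + 1e-6)
        self.initialized = True

    def forward(self, x: Tensor):
        self.maybe_init(x.data)
        y = (x + self.bias) * self.logs.exp()
        logdet = self.logs.sum() * float(_spatial(x))
        return y, logdet

    def inverse(self, y: Tensor):
        x = y * (-self.logs).exp() - self.bias
        logdet = self.logs.sum() * float(_spatial(y))
        return x, logdet

    def params(self):
        return {"bias": self.bias, "logs": self.logs}


class _Inv1x1:
    """Invertible 1x1x1 convolution, LU-parameterized for O(C) log-det."""

    def __init__(self, n_channels: int, rng: np.random.Generator, identity_init: bool):
        c = n_channels
        if identity_init:
            w = np.eye(c)
        else:
            q, _ = np.linalg.qr(rng.standard_normal((c, c)))
            w = q
        p, low, up = scipy.linalg.lu(w)
        s = np.diag(up).copy()
        self.perm = p  # fixed
        self.sign = np.sign(s)  # fixed
        self.lower = Tensor(np.tril(low, -1), requires_grad=True)
        self.upper = Tensor(np.triu(up, 1), requires_grad=True)
        self.log_s = Tensor(np.log(np.abs(s)), requires_grad=True)
        self._lmask = np.tril(np.ones((c, c)), -1)
        self._umask = np.triu(np.ones((c, c)), 1)
        self._eye = np.eye(c)

    def _weight(self) -> Tensor:
        c = self._eye.shape[0]
        low = self.lower * self._lmask + self._eye
        up = self.upper * self._umask + self._eye * (self.sign * self.log_s.exp().reshape(1, c))
        return matmul_last(Tensor(self.perm), matmul_last(low, up))

    def forward(self, x: Tensor):
        y = matmul_last(x, self._weight())
        logdet = self.log_s.sum() * float(_spatial(x))
        return y, logdet

    def inverse(self, y: Tensor):
        # parameters are constants in the decode direction
        w_inv = np.linalg.inv(self._weight().data)
        x = matmul_last(y, Tensor(w_inv))
        logdet = self.log_s.sum() * float(_spatial(y))
        return x, logdet

    def params(self):
        return {"lower": self.lower, "upper": self.upper, "log_s": self.log_s}

    def extra_state(self):
        return {"perm": self.perm, "sign": self.sign}


class _ZeroConvNet:
    """conv3x3 -> relu -> conv1x1 -> relu -> conv3x3, last layer zero-init.

    The zero-initialized final layer starts the flow near the identity
    (up to the constant coupling scale sigmoid(2) + eps).
    """

    def __init__(self, c_in: int, width: int, c_out: int, rng: np.random.Generator):
        def he(k, cin, cout):
            return rng.standard_normal((k, k, k, cin, cout)) * np.sqrt(2.0 / (cin * k ** 3))

        self.w1 = Tensor(he(3, c_in, width), requires_grad=True)
        self.b1 = Tensor(np.zeros(width), requires_grad=True)
        self.w2 = Tensor(he(1, width, width), requires_grad=True)
        self.b2 = Tensor(np.zeros(width), requires_grad=True)
        self.w3 = Tensor(np.zeros((3, 3, 3, width, c_out)), requires_grad=True)
        self.b3 = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        h = conv3d(x, self.w1, self.b1).relu()
        h = conv3d(h, self.w2, self.b2).relu()
        return conv3d(h, self.w3, self.b3)

    def params(self):
        return {"w1": self.w1, "b1": self.b1, "w2": self.w2,
                "b2": self.b2, "w3": self.w3, "b3": self.b3}


class _Coupling:
    """Affine coupling: first half passes through and parameterizes the
    scale/shift applied to the second half."""

    def __init__(self, n_channels: int, width: int, eps: float, rng):
        if n_channels < 2:
            raise ValueError("affine coupling needs >= 2 channels")
        self.c1 = n_channels // 2
        self.c2 = n_channels - self.c1
        self.eps = eps
        self.net = _ZeroConvNet(self.c1, width, 2 * self.c2, rng)

    def _scale_shift(self, x1: Tensor):
        out = self.net(x1)
        shift = out[..., :self.c2]
        raw = out[..., self.c2:]
        scale = (raw + 2.0).sigmoid() + self.eps
        return scale, shift

    def forward(self, x: Tensor):
        x1, x2 = x[..., :self.c1], x[..., self.c1:]
        scale, shift = self._scale_shift(x1)
        y2 = x2 * scale + shift
        logdet = scale.log().sum(axis=(1, 2, 3, 4))
        return concat([x1, y2], axis=-1), logdet

    def inverse(self, y: Tensor):
        y1, y2 = y[..., :self.c1], y[..., self.c1:]
        scale, shift = self._scale_shift(y1)
        x2 = (y2 - shift) / scale
        logdet = scale.log().sum(axis=(1, 2, 3, 4))
        return concat([y1, x2], axis=-1), logdet

    def params(self):
        return self.net.params()


def _squeeze(x: Tensor, f: tuple) -> Tensor:
    fd, fh, fw = f
    b, d, h, w, c = x.shape
    x = x.reshape(b, d // fd, fd, h // fh, fh, w // fw, fw, c)
    x = x.transpose((0, 1, 3, 5, 2, 4, 6, 7))
    return x.reshape(b, d // fd, h // fh, w // fw, fd * fh * fw * c)


def _unsqueeze(x: Tensor, f: tuple) -> Tensor:
    fd, fh, fw = f
    b, d, h, w, c = x.shape
    c_out = c // (fd * fh * fw)
    x = x.reshape(b, d, h, w, fd, fh, fw, c_out)
    x = x.transpose((0, 1, 4, 2, 5, 3, 6, 7))
    return x.reshape(b, d * fd, h * fh, w * fw, c_out)


def _gaussian_logp(z: Tensor, mean, logs) -> Tensor:
    """Diagonal-Gaussian log density summed over non-batch axes."""
    z = as_tensor(z)
    mean, logs = as_tensor(mean), as_tensor(logs)
    ll = (-0.5 * _LOG2PI) - logs - 0.5 * ((z - mean) * (-logs).exp()) ** 2
    return ll.sum(axis=tuple(range(1, z.ndim)))


class _Split:
    """Factor out half the channels with a conditional Gaussian prior."""

    def __init__(self, n_channels: int, rng):
        self.c1 = n_channels // 2
        self.c2 = n_channels - self.c1
        # zero-initialized prior net => N(0, 1) at the start of training
        self.w = Tensor(np.zeros((3, 3, 3, self.c1, 2 * self.c2)), requires_grad=True)
        self.b = Tensor(np.zeros(2 * self.c2), requires_grad=True)

    def _prior(self, h1: Tensor):
        out = conv3d(h1, self.w, self.b)
        return out[..., :self.c2], out[..., self.c2:]  # mean, logs

    def forward(self, h: Tensor):
        h1, z = h[..., :self.c1], h[..., self.c1:]
        mean, logs = self._prior(h1)
        return h1, z, _gaussian_logp(z, mean, logs)

    def inverse(self, h1: Tensor, z: Tensor):
        mean, logs = self._prior(h1)
        return concat([h1, as_tensor(z)], axis=-1), _gaussian_logp(z, mean, logs)

    def sample_z(self, h1: Tensor, temperature: float, rng: np.random.Generator):
        mean, logs = self._prior(h1)
        noise = rng.standard_normal(mean.shape)
        return mean.data + temperature * np.exp(logs.data) * noise

    def params(self):
        return {"w": self.w, "b": self.b}


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class Glow3D:
    """Multi-scale 3D flow; see module docstring."""

    def __init__(self, config: FlowConfig):
        self.config = config
        self.meta = {"bits_stage": None, "epoch": None}
        rng = np.random.default_rng(config.seed)
        f = config.squeeze_factor
        fprod = int(np.prod(f))
        d, h, w, c = config.shape
        self.levels = []
        self.z_shapes = []
        for k in range(config.levels):
            d, h, w = d // f[0], h // f[1], w // f[2]
            c = c * fprod
            steps = []
            for _ in range(config.depth):
                steps.append({
                    "actnorm": _ActNorm(c, config.identity_init),
                    "perm": (_Inv1x1(c, rng, config.identity_init)
                             if config.permutation == "inv1x1" else None),
                    "coupling": _Coupling(c, config.width, config.eps, rng),
                })
            split = None
            if k < config.levels - 1:
                split = _Split(c, rng)
                self.z_shapes.append((d, h, w, c - c // 2))
                c = c // 2
            else:
                self.z_shapes.append((d, h, w, c))
            self.levels.append({"steps": steps, "split": split})
        # learned top prior (mu_theta, log Sigma_theta); zeros => N(0, I)
        top_shape = self.z_shapes[-1]
        self.top_mean = Tensor(np.zeros(top_shape), requires_grad=config.learn_top)
        self.top_logs = Tensor(np.zeros(top_shape), requires_grad=config.learn_top)

    # -- parameters ------------------------------------------------------
    def named_params(self) -> dict:
        out = {}
        for li, level in enumerate(self.levels):
            for si, step in enumerate(level["steps"]):
                for mod_name in ("actnorm", "perm", "coupling"):
                    mod = step[mod_name]
                    if mod is None:
                        continue
                    for pname, p in mod.params().items():
                        out[f"L{li}.S{si}.{mod_name}.{pname}"] = p
            if level["split"] is not None:
                for pname, p in level["split"].params().items():
                    out[f"L{li}.split.{pname}"] = p
        if self.config.learn_top:
            out["top.mean"] = self.top_mean
            out["top.logs"] = self.top_logs
        return out

    def params(self):
        return list(self.named_params().values())

    def set_requires_grad(self, flag: bool) -> None:
        for p in self.named_params().values():
            p.requires_grad = bool(flag)

    @property
    def top_prior(self):
        """(mu_theta, Sigma_theta) of the top latent prior."""
        return self.top_mean.data.copy(), np.exp(self.top_logs.data)

    # -- core transforms -------------------------------------------------
    def _check_shape(self, x):
        if tuple(x.shape[1:]) != self.config.shape:
            raise ValueError(
                f"input shape {tuple(x.shape[1:])} != configured {self.config.shape}")

    def encode(self, x):
        """x (B,D,H,W,C) -> (latents z_1..z_K, logdet, log p(x)); all Tensors."""
        x = as_tensor(x)
        if x.ndim == 4:
            x = x.reshape((1,) + tuple(x.shape))
        self._check_shape(x)
        h = x
        logdet = Tensor(np.zeros(x.shape[0]))
        logp = Tensor(np.zeros(x.shape[0]))
        zs = []
        for level in self.levels:
            h = _squeeze(h, self.config.squeeze_factor)
            for step in level["steps"]:
                h, ld = step["actnorm"].forward(h)
                logdet = logdet + ld
                if step["perm"] is not None:
                    h, ld = step["perm"].forward(h)
                    logdet = logdet + ld
                h, ld = step["coupling"].forward(h)
                logdet = logdet + ld
            if level["split"] is not None:
                h, z, lp = level["split"].forward(h)
                logp = logp + lp
                zs.append(z)
        zs.append(h)
        logp = logp + _gaussian_logp(h, self.top_mean, self.top_logs)
        if not np.all(np.isfinite(logp.data)):
            raise FloatingPointError("non-finite log-likelihood in encode")
        return zs, logdet, logp + logdet

    def decode(self, zs):
        """Latents z_1..z_K -> (x, log p(x)); exact inverse of encode."""
        zs = [as_tensor(z) for z in zs]
        if len(zs) != self.config.levels:
            raise ValueError(f"expected {self.config.levels} latent levels, got {len(zs)}")
        for z, shape in zip(zs, self.z_shapes):
            if tuple(z.shape[1:]) != shape:
                raise ValueError(f"latent shape {tuple(z.shape[1:])} != expected {shape}")
        h = zs[-1]
        logp = _gaussian_logp(h, self.top_mean, self.top_logs)
        logdet = Tensor(np.zeros(h.shape[0]))
        for k in range(self.config.levels - 1, -1, -1):
            level = self.levels[k]
            if level["split"] is not None:
                h, lp = level["split"].inverse(h, zs[k])
                logp = logp + lp
            for step in reversed(level["steps"]):
                h, ld = step["coupling"].inverse(h)
                logdet = logdet + ld
                if step["perm"] is not None:
                    h, ld = step["perm"].inverse(h)
                    logdet = logdet + ld
                h, ld = step["actnorm"].inverse(h)
                logdet = logdet + ld
            h = _unsqueeze(h, self.config.squeeze_factor)
        return h, logp + logdet

    # -- likelihood interface -------------------------------------------
    def log_likelihood(self, x) -> np.ndarray:
        """log p_theta(x) in nats, per sample (no gradient bookkeeping)."""
        self.set_requires_grad(False)
        try:
            _, _, logp = self.encode(np.asarray(x, dtype=np.float64))
        finally:
            self.set_requires_grad(True)
        return logp.data.copy()

    def nll(self, batch) -> float:
        """Mean negative log-likelihood (nats) over a batch (B,D,H,W,C)."""
        batch = np.asarray(batch, dtype=np.float64)
        if batch.ndim == 4:
            batch = batch[None]
        if batch.shape[0] == 0:
            raise ValueError("empty batch")
        return float(-self.log_likelihood(batch).mean())

    def nll_tensor(self, batch) -> Tensor:
        """NLL as a graph node for training."""
        _, _, logp = self.encode(batch)
        return -logp.mean()

    def sample(self, temperature: float = 0.5, seed: int | None = None, n: int = 1):
        """Draw n volumes: z_K ~ N(mu, T^2 Sigma^2), intermediate z_k from the
        tempered conditional priors; returns (x ndarray, latents list)."""
        if temperature < 0:
            raise ValueError("temperature must be >= 0")
        rng = np.random.default_rng(seed)
        self.set_requires_grad(False)
        try:
            top = (self.top_mean.data
                   + temperature * np.exp(self.top_logs.data)
                   * rng.standard_normal((n,) + self.z_shapes[-1]))
            h = as_tensor(top)
            zs_rev = [top]
            for k in range(self.config.levels - 1, -1, -1):
                level = self.levels[k]
                if level["split"] is not None:
                    z_k = level["split"].sample_z(h, temperature, rng)
                    h, _ = level["split"].inverse(h, z_k)
                    zs_rev.append(z_k)
                for step in reversed(level["steps"]):
                    h, _ = step["coupling"].inverse(h)
                    if step["perm"] is not None:
                        h, _ = step["perm"].inverse(h)
                    h, _ = step["actnorm"].inverse(h)
                h = _unsqueeze(h, self.config.squeeze_factor)
            zs = list(reversed(zs_rev))
        finally:
            self.set_requires_grad(True)
        return h.data.copy(), zs

    def initialize_actnorm(self, batch) -> None:
        """Data-dependent actnorm initialization from one batch."""
        self.set_requires_grad(False)
        try:
            self.encode(np.asarray(batch, dtype=np.float64))
        finally:
            self.set_requires_grad(True)

    # -- persistence -----------------------------------------------------
    def save(self, path: str) -> None:
        """Bit-exact checkpoint: config, metadata and all arrays in one file."""
        arrays = {name: p.data for name, p in self.named_params().items()}
        arrays["top.mean"] = self.top_mean.data
        arrays["top.logs"] = self.top_logs.data
        for li, level in enumerate(self.levels):
            for si, step in enumerate(level["steps"]):
                if step["perm"] is not None:
                    for key, val in step["perm"].extra_state().items():
                        arrays[f"L{li}.S{si}.perm._{key}"] = val
        header = {"config": asdict(self.config), "meta": self.meta}
        with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
            zf.writestr("header.json", json.dumps(header))
            buf = io.BytesIO()
            np.savez(buf, **arrays)
            zf.writestr("arrays.npz", buf.getvalue())

    @classmethod
    def load(cls, path: str) -> "Glow3D":
        with zipfile.ZipFile(path) as zf:
            header = json.loads(zf.read("header.json"))
            with np.load(io.BytesIO(zf.read("arrays.npz"))) as npz:
                arrays = {k: npz[k] for k in npz.files}
        model = cls(FlowConfig(**header["config"]))
        model.meta = header["meta"]
        named = model.named_params()
        for name, p in named.items():
            p.data = arrays[name].astype(np.float64)
        model.top_mean.data = arrays["top.mean"].astype(np.float64)
        model.top_logs.data = arrays["top.logs"].astype(np.float64)
        for li, level in enumerate(model.levels):
            for si, step in enumerate(level["steps"]):
                step["actnorm"].initialized = True
                if step["perm"] is not None:
                    step["perm"].perm = arrays[f"L{li}.S{si}.perm._perm"]
                    step["perm"].sign = arrays[f"L{li}.S{si}.perm._sign"]
        return model

    def copy(self) -> "Glow3D":
        """Deep copy via the checkpoint format (bit-exact)."""
        clone = Glow3D(self.config)
        clone.meta = dict(self.meta)
        mine = self.named_params()
        for name, p in clone.named_params().items():
            p.data = mine[name].data.copy()
        clone.top_mean.data = self.top_mean.data.copy()
        clone.top_logs.data = self.top_logs.data.copy()
        for lc, ls in zip(clone.levels, self.levels):
            for sc, ss in zip(lc["steps"], ls["steps"]):
                sc["actnorm"].initialized = ss["actnorm"].initialized
                if sc["perm"] is not None:
                    sc["perm"].perm = ss["perm"].perm.copy()
                    sc["perm"].sign = ss["perm"].sign.copy()
        return clone
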