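"""Progressive NLL training of the flow over increasing bit depths.

The curriculum trains the same model first on coarsely quantized volumes
(2 bits) and then on progressively finer gradations (3, 4, 8 bits); model
parameters carry over between stages while the optimizer state resets.
The reference full-scale stage list is (2,96), (3,324), (4,24), (8,144)
epochs; desk-scale runs use the same structure with few epochs per stage.

Training minimizes the mean negative log-likelihood (nats) with Adam under
a linear learning-rate warmup to the steady rate (1e-4 at full scale).
Validation NLL is monitored each epoch; the checkpoint with the best
validation NLL is kept and training stops early after a patience of
non-improving epochs.  Dequantization noise is on for training inputs and
off (bin centers) for validation so the monitored NLL is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .io_preprocess import quantize_bits, to_model_space
from .glow3d import Glow3D

__all__ = ["ProgressiveSchedule", "Adam", "early_stop_monitor",
           "train_stage", "run_schedule", "FULL_SCALE_STAGES", "DESK_STAGES"]

#: full-scale stage list (bits, epochs)
FULL_SCALE_STAGES = ((2, 96), (3, 324), (4, 24), (8, 144))
#: desk-scale default for CPU-sized phantom runs
DESK_STAGES = ((2, 2), (3, 2), (4, 2), (8, 4))


@dataclass
class ProgressiveSchedule:
    stages: tuple = FULL_SCALE_STAGES  # ordered (bits, epochs)
    learning_rate: float = 1.0e-4  # steady-state rate
    warmup_steps: int = 10
    batch_size: int = 1  # full scale trains 1 per device; desk default 4
    patience: int = 10
    grad_clip: float = 100.0  # global-norm clip, 0 disables
    seed: int = 0

    def __post_init__(self):
        bits = [b for b, _ in self.stages]
        if bits != sorted(bits) or len(set(bits)) != len(bits):
            raise ValueError("stage bit depths must be strictly increasing")
        if any(e < 0 for _, e in self.stages):
            raise ValueError("stage epochs must be >= 0")
        if any(not 1 <= b <= 8 for b in bits):
            raise ValueError("stage bits must be in 1..8")


class Adam:
    """Adam with linear learning-rate warmup to the steady rate."""

    def __init__(self, params, lr: float, warmup_steps: int = 0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.warmup = max(0, int(warmup_steps))
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def current_lr(self) -> float:
        """Rate applied at the next step (warmup ramps over `warmup` steps)."""
        if self.warmup and self.t < self.warmup:
            return self.lr * (self.t + 1) / self.warmup
        return self.lr

    def step(self, grad_clip: float = 0.0) -> None:
        lr = self.current_lr()
        self.t += 1
        grads = [np.zeros_like(p.data) if p.grad is None else p.grad
                 for p in self.params]
        if grad_clip:
            gnorm = np.sqrt(sum(float((g * g).sum()) for g in grads))
            if gnorm > grad_clip:
                grads = [g * (grad_clip / gnorm) for g in grads]
        for i, (p, g) in enumerate(zip(self.params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def early_stop_monitor(val_nll_history, patience: int = 10) -> dict:
    """Decide whether to save / stop given the validation-NLL history.

    Returns ``{"save": bool, "stop": bool, "best_index": int}``: save when
    the last entry is a new strict minimum; stop when `patience` epochs have
    passed without improvement over the minimum so far.
    """
    hist = list(val_nll_history)
    if not hist:
        raise ValueError("history must be nonempty")
    best_index = int(np.argmin(hist))
    save = best_index == len(hist) - 1
    stop = (len(hist) - 1 - best_index) >= patience
    return {"save": save, "stop": stop, "best_index": best_index}


def _model_space_batches(vols, bits, batch_size, rng, dequantize):
    """Quantize to `bits`, map to [0,1) model space, yield shuffled batches."""
    arrays = []
    for i, vol in enumerate(vols):
        q = quantize_bits(vol, bits)
        seed = None if not dequantize else int(rng.integers(2 ** 31))
        arrays.append(to_model_space(q, dequantize=dequantize, seed=seed).voxels)
    arrays = np.stack(arrays)
    order = rng.permutation(len(arrays)) if dequantize else np.arange(len(arrays))
    for start in range(0, len(arrays), batch_size):
        yield arrays[order[start:start + batch_size]]


def _val_nll(model: Glow3D, val_vols, bits: int, batch_size: int) -> float:
    total, count = 0.0, 0
    rng = np.random.default_rng(0)  # unused (no dequant)
    for batch in _model_space_batches(val_vols, bits, batch_size, rng, dequantize=False):
        total += -model.log_likelihood(batch).sum()
        count += len(batch)
    return total / count


def train_stage(model: Glow3D, train_vols, val_vols, bits: int, epochs: int,
                schedule: ProgressiveSchedule, log=None, stage_seed: int = 0):
    """Train one bit-depth stage; returns (best-val checkpoint, history).

    `train_vols` / `val_vols` are 8-bit :class:`Volume8` volumes; they are
    quantized to `bits` here.  On a non-finite loss the stage aborts and the
    last finite checkpoint is returned.
    """
    if epochs == 0:
        return model, []
    rng = np.random.default_rng([schedule.seed, stage_seed])
    opt = Adam(model.params(), lr=schedule.learning_rate,
               warmup_steps=schedule.warmup_steps)
    tb2 = 1.0 / (np.log(2.0) * np.prod(model.config.shape[:3]))
    best = model.copy()
    history = []
    val_hist = []
    for epoch in range(epochs):
        train_nll = []
        for batch in _model_space_batches(train_vols, bits, schedule.batch_size,
                                          rng, dequantize=True):
            opt.zero_grad()
            try:
                loss = model.nll_tensor(batch)
            except FloatingPointError:
                loss = None
            if loss is None or not np.isfinite(loss.data):
                if log is not None:
                    log({"stage_bits": bits, "epoch": epoch, "event": "abort-nonfinite"})
                return best, history
            loss.backward()
            opt.step(grad_clip=schedule.grad_clip)
            train_nll.append(float(loss.data))
        val_nll = _val_nll(model, val_vols, bits, schedule.batch_size)
        val_hist.append(val_nll)
        row = {"stage_bits": bits, "epoch": epoch,
               "train_nll": float(np.mean(train_nll)), "val_nll": val_nll,
               "bits_per_dim": val_nll * tb2, "lr": opt.current_lr()}
        history.append(row)
        if log is not None:
            log(row)
        decision = early_stop_monitor(val_hist, patience=schedule.patience)
        if decision["save"]:
            best = model.copy()
            best.meta = {"bits_stage": bits, "epoch": epoch}
        if decision["stop"]:
            break
    return best, history


def run_schedule(model: Glow3D, schedule: ProgressiveSchedule,
                 train_vols, val_vols, log_path: str | None = None) -> Glow3D:
    """Execute the staged curriculum, warm-starting each stage from the
    previous best checkpoint.  Actnorm is data-initialized from the first
    batch of the first stage."""
    log_fh = open(log_path, "a") if log_path else None

    def log(row):
        if log_fh:
            log_fh.write(json.dumps(row) + "\n")
            log_fh.flush()

    try:
        first_bits = schedule.stages[0][0]
        rng = np.random.default_rng([schedule.seed, 999])
        init_batch = next(_model_space_batches(
            train_vols, first_bits, min(len(train_vols), max(schedule.batch_size, 4)),
            rng, dequantize=True))
        model.initialize_actnorm(init_batch)
        for stage_idx, (bits, epochs) in enumerate(schedule.stages):
            model, _ = train_stage(model, train_vols, val_vols, bits, epochs,
                                   schedule, log=log, stage_seed=stage_idx)
    finally:
        if log_fh:
            log_fh.close()
    return model
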