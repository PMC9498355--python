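"""Volume agreement metrics (SSIM, PSNR, MAE, NRMSE) and cohort reports.

Conventions: metrics are computed on the unit [0, 1] intensity scale.
SSIM is the Wang structural similarity with a full-3D 7^3 uniform sliding
window, K1 = 0.01, K2 = 0.03 and data range 1.0 (delegated to
scikit-image).  PSNR = 10 log10(1 / MSE) dB, capped at 100 dB for an exact
match.  NRMSE normalizes the RMSE by the intensity range of the ground
truth.  Cohort summaries report the mean and the population variance
(n divisor) of each metric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

from .io_preprocess import Volume8

__all__ = ["ssim3", "psnr", "mae", "nrmse", "MetricsReport", "evaluate_dataset"]

PSNR_CAP = 100.0  # dB sentinel for an exact (zero-MSE) match
METRIC_NAMES = ("ssim", "psnr", "mae", "nrmse")


def _unit_array(x) -> np.ndarray:
    if isinstance(x, Volume8):
        x = x.to_unit().voxels
    a = np.asarray(x, dtype=np.float64)
    if a.ndim == 4 and a.shape[-1] == 1:
        a = a[..., 0]
    return a


def _pair(pred, truth):
    p, t = _unit_array(pred), _unit_array(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return p, t


def ssim3(pred, truth, win_size: int = 7, data_range: float = 1.0) -> float:
    """Structural similarity with a 3D sliding window."""
    p, t = _pair(pred, truth)
    win = min(win_size, *(s if s % 2 else s - 1 for s in p.shape))
    return float(structural_similarity(
        t, p, win_size=win, data_range=data_range,
        gaussian_weights=False, K1=0.01, K2=0.03))


def psnr(pred, truth, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; capped for identical inputs."""
    p, t = _pair(pred, truth)
    mse = float(np.mean((p - t) ** 2))
    if mse <= data_range ** 2 * 10 ** (-PSNR_CAP / 10.0):
        return PSNR_CAP
    return float(10.0 * np.log10(data_range ** 2 / mse))


def mae(pred, truth) -> float:
    """Mean absolute error."""
    p, t = _pair(pred, truth)
    return float(np.mean(np.abs(p - t)))


def nrmse(pred, truth) -> float:
    """RMSE normalized by the ground-truth intensity range (max - min)."""
    p, t = _pair(pred, truth)
    rng = float(t.max() - t.min())
    if rng == 0.0:
        raise ValueError("NRMSE undefined for a constant ground truth")
    return float(np.sqrt(np.mean((p - t) ** 2)) / rng)


@dataclass
class MetricsReport:
    """Per-case metrics plus cohort mean and population variance."""

    per_case: list = field(default_factory=list)  # dicts keyed by METRIC_NAMES
    mean: dict = field(default_factory=dict)
    variance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"per_case": self.per_case, "mean": self.mean,
                           "variance": self.variance}, indent=2, sort_keys=True)

    def to_text(self) -> str:
        """Aligned table: one metric per row, mean with variance in brackets."""
        lines = [f"{'Metric':8s}  {'Mean':>12s}  {'Variance':>12s}"]
        for name in METRIC_NAMES:
            lines.append(f"{name.upper():8s}  {self.mean[name]:12.6g}  "
                         f"({self.variance[name]:.6g})")
        return "\n".join(lines)


def evaluate_dataset(pairs) -> MetricsReport:
    """Compute all metrics for (prediction, truth) pairs and summarize."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("need at least one (prediction, truth) pair")
    report = MetricsReport()
    for pred, truth in pairs:
        report.per_case.append({
            "ssim": ssim3(pred, truth), "psnr": psnr(pred, truth),
            "mae": mae(pred, truth), "nrmse": nrmse(pred, truth)})
    for name in METRIC_NAMES:
        vals = np.array([c[name] for c in report.per_case])
        report.mean[name] = float(vals.mean())
        report.variance[name] = float(vals.var())  # population variance
    return report
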