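# flowct

MAP reconstruction of a 3D CT volume from **one or two 2D projection
images**, using an exact-likelihood 3D normalizing-flow prior.

## The problem

Ultra-sparse-view CT tries to recover a volume x from a single (uniplanar)
or two orthogonal (biplanar) projections y^j — far too few views for
classical reconstruction.  `flowct` treats this as maximum a posteriori
estimation,

    x̂ = argmax_x  log p(y | x) + log p(x),

with a Gaussian projection-consistency likelihood
`log p(y|x) ∝ -Σ_j ‖y^j − P_j x‖² / (2σ²)` (P_j is the axis-mean forward
projection; the ultra-low-dose protocol adds N(0, σ²=100) pixel noise) and
a prior p(x) learned by a multi-scale invertible flow (3D GLOW: actnorm,
invertible 1×1×1 convolutions, affine couplings with the stabilized scale
`sigmoid(h+2)+ε`).  Because the flow gives exact log-likelihoods and an
invertible decoder G, the posterior is ascended in latent space:

    z ← z − α(n) ∇_z [ Σ_j ‖y^j − P_j G(z)‖²/(2σ²) − Tb² log p(G(z)) ],

with α(n) = A(1−e^(−0.01n)), Tb² = (ln2·D·H·W)⁻¹ (bits-per-dim weighting),
initialization from a temperature-0.5 sample, and stopping when the
residual falls to 3 gray levels RMS per pixel (‖r‖² ≤ 3²·N·H·W), the
iteration cap (1000) is reached, or the latent step stalls.  The prior is
trained progressively — 2-, 3-, 4-, then 8-bit quantized volumes — which
accelerates NLL convergence.

Since real hospital CT cohorts are not redistributable, the package ships
a phantom generator (jittered ellipsoid chests: body, lungs, heart, spine,
scanner bed) that provides a learnable image distribution for training and
evaluation; see `docs/methods.md` for what that does and does not
demonstrate.

The gradient engine is a self-contained reverse-mode autodiff tape over
numpy (`flowct.tape`), finite-difference-verified, serving both training
and reconstruction.

## Worked example

```python
from flowct.phantoms import PhantomSpec, generate_phantom, make_dataset
from flowct.study import DeskStudyConfig, train_desk_prior
from flowct.projection import project
from flowct.map_recon import ReconSettings, reconstruct
from flowct.metrics import ssim3, psnr

cfg = DeskStudyConfig(seed=7)          # 16³ phantoms, 100 subjects
model, test_vols, diag = train_desk_prior(cfg)   # ~10 s on one CPU

truth = test_vols[0]
projs = [project(truth, v) for v in ("coronal", "sagittal")]
xhat, trace = reconstruct(projs, model, ReconSettings.desk("standard", seed=11))
print(trace.stop_reason, len(trace.rows))
print("SSIM", round(ssim3(xhat, truth.to_unit()), 4),
      "PSNR", round(psnr(xhat, truth.to_unit()), 2))
```

prints

```
residual-met 47
SSIM 0.8641 PSNR 24.06
```

i.e. the optimization met the 3-gray-level residual criterion after 47
latent-space iterations, and the reconstructed volume agrees with the
held-out ground truth at SSIM ≈ 0.86 — versus 0.19 for the temperature-0.5
initial guess.  Two views beat one, and noisy (ultra-low-dose) inputs cost
accuracy but still end far above the initial guess; the study driver
`flowct.study.run_desk_study` reproduces the whole comparison table.

The same functionality is scriptable from the shell:

```bash
flowct simulate-phantoms --n 50 --size 16 --seed 7 --out-dir data/
flowct train --data-dir data/ --out-dir run/ --seed 7
flowct project --volume data/vol_0003.nii.gz --views coronal,sagittal --out-dir run/
mkdir -p run/pred
flowct reconstruct --model run/model.ckpt \
    --projections run/vol_0003_coronal.png,run/vol_0003_sagittal.png \
    --protocol standard --seed 7 --out run/pred/vol_0003.nii.gz
flowct evaluate --pred-dir run/pred --truth-dir data/ --out run/report.json
```

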