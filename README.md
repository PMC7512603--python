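# auxgibbs

Auxiliary-variable (data augmentation) Gibbs samplers for high-dimensional
Bayesian inverse problems, with two complete image-restoration pipelines
exercised entirely on synthetic data.

## The problem

Bayesian image restoration reduces to sampling a posterior whose negative
log-density is

    J(x) = Φ(Hx; z) + Ψ(Vx),

where `H` is a blur/observation operator and `V` a prior transform (wavelet
analysis, discrete Laplacian, ...).  When the likelihood and prior precision
matrices — `HᵀΛH` and `VᵀΩV` — cannot be diagonalized in the same basis,
neither direct Gaussian sampling nor well-preconditioned
Metropolis–Hastings scales to images.  The remedy implemented here augments
the model with a Gaussian auxiliary variable `v` whose conditional law is
chosen so that one source of coupling moves out of the x-conditional:

* **Alternative I** removes the noise precision Λ:
  `v | x ~ N(ΓHx, Γ)`, `Γ = (1/μ)I − Λ`, valid for `μ‖Λ‖_S < 1`; the
  conditional of `x` becomes a *white-noise* restoration problem
  `J(x|v) = (1/2μ)‖Hx − μ(Λz + v)‖² + Ψ(Vx)`.
* **Alternative II** removes the full coupling `HᵀΛH`:
  `v | x ~ N(Γx, Γ)`, `Γ = (1/μ)I − HᵀΛH`; the conditional becomes a
  *denoising* problem `J(x|v) = (1/2μ)‖x − μ(v + HᵀΛz)‖² + Ψ(Vx)` that
  factorizes whenever the prior does.

Alternating `v | x` and `x | v` is a two-block Gibbs sampler whose
x-marginal is exactly the original posterior.  The auxiliary draw itself
has a structured covariance of the form `(1/μ)I − HᵀΛH`, which this package
samples *exactly* (no conjugate-gradient approximation) through covariance-
splitting identities for circulant operators, tight frames (`HHᵀ = νI`) and
operator products `H = MP`.

The same construction extends to scale mixtures of Gaussian noise (per-pixel
random variances `σ_i`), where the step size `μ(σ) = ε·min σ_i²` must be
recomputed every sweep and the `σ` update is drawn from its v-collapsed
conditional inside a partially collapsed Gibbs sampler (PCGS) — valid only
for specific sweep orderings, which the package validates.

## What is in the box

| module | contents |
|---|---|
| `auxgibbs.linops` | operator algebra: circulant, diagonal, orthonormal wavelet frame, per-channel block, composite; spectral norms; cross-channel block selectors |
| `auxgibbs.struct_gauss` | exact structured Gaussian samplers + dense Cholesky oracle |
| `auxgibbs.da_core` | DA constructions (Alternatives I/II, four fully-Gaussian variants), two-block Gibbs loop |
| `auxgibbs.scale_mixture` | mixing-variable machinery `D(σ)`, `μ(σ)`, PCGS schedule validation |
| `auxgibbs.mh_kernels` | random-walk and MALA kernels with burn-in step-size adaptation |
| `auxgibbs.app_multichannel` | wavelet-domain restoration of B-channel images under a generalized multivariate exponential power (GMEP) prior with hyperparameter sampling |
| `auxgibbs.app_mixednoise` | deblurring under two-term mixed (impulse-like) Gaussian noise, AuxV1/AuxV2 PCGS schedules |
| `auxgibbs.synthdata` | smooth-prior random fields, GMEP channel stacks, blur + noise degradation |
| `auxgibbs.diagnostics` | chain traces, mean-squared-jump (MSJ), SNR/PSNR/BSNR/SSIM |
| `auxgibbs.cli` | `auxgibbs simulate / restore-mixed / restore-mci / metrics / diagnostics` |

## Worked example

Deblur a synthetic 128×128 image drawn from the Gaussian smoothness prior
(`p(x|γ) ∝ γ^{Q/2} exp(−(γ/2)‖Lx‖²)`, `L = 0.01·I − ∇²`, γ = 5.3×10⁻³),
blurred with a 39×39 Gaussian kernel (std 4) and corrupted by two-term
mixed noise (κ₁ = 13, κ₂ = 40, β = 0.35):

```python
import numpy as np
from auxgibbs.linops import CirculantMap2D
from auxgibbs.synthdata import (DegradationSpec, degrade,
                                gaussian_kernel, gen_smooth_image)
from auxgibbs.app_mixednoise import MixedNoiseConfig, run_auxv1
from auxgibbs.diagnostics import image_metrics

shape = (128, 128)
x = gen_smooth_image(shape, gamma=5.30e-3, delta_L=0.01, seed=11)
spec = DegradationSpec(gaussian_kernel(39, 4.0), ("mixed", 0.35, 13.0, 40.0))
z, truth = degrade(x, spec, rng=12)

H = CirculantMap2D(spec.kernel, shape)
cfg = MixedNoiseConfig(n_iter=3000, burn_in=2000)
mmse, summary, trace = run_auxv1(z, H, cfg, rng=13)

for k in ("kappa1", "kappa2", "beta", "gamma"):
    print(k, round(summary[k]["mean"], 5))
print("PSNR degraded", round(image_metrics(x, z)["psnr"], 2),
      "-> restored", round(image_metrics(x, mmse)["psnr"], 2))
```

Output:

```
kappa1 13.25569
kappa2 40.12181
beta 0.34806
gamma 0.00525
PSNR degraded 19.09 -> restored 27.97
```

The posterior means recover the generating noise levels (13 / 40), the
impulse probability (0.35) and the smoothness precision (5.3×10⁻³), and the
MMSE estimate (the average of the post-burn-in samples) gains ≈ 9 dB PSNR
over the observed image.  `summary["msj"]` reports the mean squared jump
between successive kept samples, the mixing diagnostic used to compare
sampler variants.

The same can be run from the shell:

```sh
auxgibbs simulate --model smooth --shape 128x128 \
    --kernel-spec gaussian:39:4 --noise mixed:0.35:13:40 --seed 11 --out sim/
auxgibbs restore-mixed --input sim/observed.tiff --kernel sim/kernel.txt \
    --iters 3000 --burn-in 2000 --seed 13 --out restored/
auxgibbs metrics sim/truth.tiff restored/restored.tiff
```

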