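# tgvtomo

Reconstruction toolkit for **optical phase-contrast photoacoustic tomography**
(PAT): recover a 3D initial acoustic pressure distribution p₀ from camera
snapshots of the propagating ultrasound field, with special emphasis on
**few-angle** acquisitions where classical inversion breaks down.

It is aimed at researchers working with projection-type PAT detection
(integrating line detectors, phase-contrast cameras) and at anyone who wants a
compact, fully tested reference implementation of TGV-regularized Radon
inversion by a primal-dual algorithm.

## The method

A camera snapshot at time T and sample rotation φ measures phase shifts
proportional to the slice-wise 2D Radon transform R of the pressure field,
P = k_pc·R[p_T].  Reconstruction proceeds in two steps:

1. **Back propagation.**  Because R intertwines the 3D and 2D Laplacians,
   R[p] obeys a 2D wave equation per angle, whose zero-initial-velocity
   solution is the Fourier multiplier cos(c_s|k|T).  Applying the same
   multiplier to 2·R[p_T] recovers the initial sinogram,
   f ≈ R[p₀] = F⁻¹[ F[2 R[p_T]] · cos(c_s|k|T) ].

2. **Variational Radon inversion.**  Solve

       min_p  μ/2 ‖R p − f‖² + TGV²_α(p),
       TGV²_α(p) = min_q α₁‖∇p − q‖ℓ1 + α₀‖E q‖ℓ1,

   by the Chambolle–Pock primal-dual iteration on the combined operator
   A(p,q) = (Rp, ∇p − q, Eq), with the projector rescaled to unit norm
   (power iteration) so that the step-size rule στ < 1/12 guarantees
   convergence (‖A‖² < 12).  Total variation (α₁‖∇p‖ℓ1) and filtered back
   projection are provided as comparison arms.  Defaults: α₁ = 1, α₀ = 2.5.

TGV preserves edges like TV but avoids TV's staircase plateaus on smoothly
varying backgrounds, and both variational methods suppress the streak
artifacts that make FBP unusable at few projection angles.

See `docs/methods.md` for discretization details, parameter guidance, and
what the synthetic experiments do and do not demonstrate.

## Worked example

Simulate a hair-loop/microsphere phantom, reconstruct from all and from a
quarter of the angles, and compare:

```python
import numpy as np
import tgvtomo as tg

geo = tg.GeometryConfig(nx=64, nz=8, n_angles=96, T=1.0)
truth = tg.make_hairloop_phantom(geo.volume_shape, n_loops=2, n_spheres=4, seed=3)

snap = tg.simulate_measurement(truth, geo, pad_factor=(4, 32), seed=1)
sino = tg.back_propagate(snap, geo)

geo24 = geo.subsample_angles(4)
sino24 = tg.back_propagate(tg.subsample_angles(snap, 4), geo24)

fbp24 = tg.fbp_reconstruct(sino24, geo24)
tgv24, _ = tg.reconstruct(sino24, geo24, tg.SolverParams(mu=4000.0, n_iter=2000))

for name, rec in [("FBP, 24 angles", fbp24), ("TGV, 24 angles", tgv24)]:
    print(f"{name}: psnr {tg.psnr(rec, truth):5.2f} dB  "
          f"ssim {tg.ssim(rec, truth):.3f}  "
          f"background std {rec[truth == 0].std():.4f}")
```

Output:

```
FBP, 24 angles: psnr 24.89 dB  ssim 0.337  background std 0.0546
TGV, 24 angles: psnr 34.97 dB  ssim 0.986  background std 0.0115
```

The TGV reconstruction at a quarter of the angles keeps the loops and spheres
sharp at ~5× lower background fluctuation and +10 dB PSNR, while FBP is
dominated by streak artifacts — the few-angle behavior the method is designed
for.

The same pipeline is scriptable from the shell
(`tgvtomo phantom | simulate | backprop | reconstruct | fbp | metrics`, or
`tgvtomo run --config experiment.yaml --out results/` for a reproducible,
manifest-tracked experiment).

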