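# Methods

`tgvtomo` reconstructs 3D initial-pressure distributions from optical
phase-contrast projection measurements of photoacoustic waves.  This note
records the model, the discretization, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## Measurement model

A pulsed laser deposits energy in absorbing structures, launching an acoustic
pressure field p(t, x) that obeys the free-space wave equation
∂²p/∂t² = c_s² Δp with initial value p₀ and zero initial velocity.  A probe
beam crossing the water tank picks up a phase shift proportional to the
pressure integrated along the beam: a camera snapshot at time T and sample
rotation φ records

    P(s, φ, z) = k_pc · R[p_T](s, φ, z),

where R is the slice-wise 2D Radon transform (line integrals over lines of
offset s and direction φ in each horizontal slice z) and
k_pc = (2π/λ_PB)(dn/dp) is the elasto-optic calibration constant (radians per
pressure·length).  Because the Radon transform intertwines the 3D Laplacian
with the 2D Laplacian in (s, z), the projection data themselves satisfy a 2D
wave equation per angle.  Two consequences drive the pipeline:

1. **Forward propagation** is a Fourier multiplier: the time-T sinogram is
   the inverse FFT of the initial sinogram's spectrum times cos(c_s |k| T).
2. **Back propagation** applies the same multiplier to twice the measured
   time-T sinogram, recovering R[p₀] plus an outgoing echo at time 2T.  The
   echo leaves a region of interest of radius ρ_roi once
   2 c_s T > ρ_support + ρ_roi.  In 2D a slowly decaying wake remains inside
   the light cone, so the recovery is approximate, improving as c_s T grows;
   measured round-trip errors on a compact blob are ≈5·10⁻² at c_s T = 0.4
   and ≈3·10⁻³ at c_s T = 1.6 (test `test_wave.py`).

Spectral propagation runs on a zero-padded grid (default factor 2 per axis,
configurable per axis) so that the periodic FFT emulates free space; the
snapshot stacks are by default kept on the padded "camera" grid, mirroring
the experimental setting where the camera field of view covers the whole wave
pattern.  Limited-view truncation can be emulated by cropping but its error
analysis is out of scope.

## Variational Radon inversion

Inverting f ≈ R[p₀] is ill-posed and, at few angles, badly underdetermined;
filtered back projection (FBP) then produces streak artifacts.  The core
method solves the Tikhonov problem

    min_p  μ/2 ‖R p − f‖² + TGV²_α(p),
    TGV²_α(p) = min_q  α₁ ‖∇p − q‖ℓ1 + α₀ ‖E q‖ℓ1,

with E the symmetrized derivative ½(∇q + ∇qᵀ), or the TV analogue
α₁‖∇p‖ℓ1.  TGV penalizes first- and second-order variation jointly: it
preserves edges like TV but does not force piecewise-constant plateaus
(the staircase effect) on smooth gradients such as tissue background.

**Defaults**: α₁ = 1 (comparability with TV), α₀ = 2.5.  μ weighs data
fidelity against regularity and is unit-dependent: it applies to the problem
*after* the projector and datum are rescaled to unit operator norm, and the
calibration constant k_pc is likewise absorbed.  Larger μ fits the data more
closely (appropriate at low noise); μ should grow roughly like 1/N_φ when
angles are removed, since the discrepancy sum shrinks proportionally.

### Discretization

The volume is piecewise constant on an N_x × N_x × N_z grid covering
[−√2/2, √2/2]² × [0, h] with the line-integration half-length normalized to
1; sinograms live on (s, φ, z) with N_s = 2N_x offset bins on [−1, 1] and
uniform angles on [0, π).  All finite differences use unit (voxel) spacing —
physical spacing is absorbed into μ and α — with forward differences and a
zero difference at the trailing boundary; the divergences on vector and
tensor fields are the exact negative adjoints (backward differences).
Symmetric tensors are stored as 6 components (xx, yy, zz, xy, xz, yz) with
off-diagonals counted twice in the inner product, so the pointwise magnitude
is the matrix Frobenius norm.

A consequence of the trailing-zero closure worth knowing: the discrete TGV of
an affine volume is *not* zero — ∇p drops to zero on the trailing planes, so
boundary terms of order N² remain against TV's N³.  The ratio vanishes under
refinement; tests assert exactly that.

### The projector

The discrete Radon transform is a pixel-footprint (strip) projector: at each
angle a square pixel's projection profile is the trapezoid obtained by
convolving two boxes of widths d|cos φ| and d|sin φ| (d the pixel size),
carrying total mass d²; each s-bin receives the bin average of that profile.
Weights are assembled once per geometry into a sparse matrix shared by
forward and adjoint, so ⟨Rp, g⟩ = ⟨p, R*g⟩ holds to machine precision — the
primal-dual convergence theory requires a true adjoint pair, which rules out
unmatched interpolating back-projectors.

Angular consistency of the projector is limited by pixelation: the staircase
projection of a pixelated image aliases against the s-bins at the ~10⁻³
level (pixel width d = √2·Δs is incommensurate with the bin width), which is
inherent to strip projectors; profiles coarse-grained over a few bins are
angle-independent to 2·10⁻³ for an isotropic phantom.

### The solver

The problem is cast as min F(u) + G(Au) with u = (p, q),
A(p, q) = (Rp, ∇p − q, Eq), F ≡ 0, and G the sum of the discrepancy and the
two ℓ1 terms, and solved by the primal-dual (Chambolle–Pock) iteration:
dual ascent with the resolvent g ← μ/(μ+σ)(g + σ(Rp̄ − f)) and pointwise
Euclidean/Frobenius ball projections for v and w; primal descent through
A* (g, v, w) = (R*g − div v, −div w − v); extragradient overrelaxation.
All state is zero-initialized.  With ‖R‖ ≤ 1 (enforced by power-iteration
rescaling) the combined operator satisfies ‖A‖² < 12, so the symmetric step
sizes σ = τ = 1/√12 − 10⁻⁶ satisfy στ‖A‖² < 1.  The TV variant drops q and w;
its operator (Rp, ∇p) only admits the cruder bound ‖A‖² ≤ 13, so TV defaults
to σ = τ = 1/√13 − 10⁻⁶.

The only stopping rule is the fixed iteration count N (an optional
relative-change early stop exists but is off by default); diagnostics can log
the data residual and the primal objective, with the TGV value evaluated by
the same primal-dual machinery on the inner minimization over q (reported as
the smaller of the last and the ergodic-average iterate, both upper bounds).
Solutions are allowed to take negative values — no positivity constraint is
imposed.

Verification is dual-route: on single-slice instances the whole objective is
assembled densely (Kronecker-product difference matrices, probed projector
columns, √2-scaled tensor basis) and solved by an independent ADMM;
primal-dual and ADMM solutions agree to ≈2·10⁻⁵ max-abs for TGV and ≈10⁻¹¹
for TV on an 8×8 grid with 6 angles, and the TGV functional value matches its
dense oracle to ≈10⁻¹⁴.

### FBP baseline

Classical parallel-beam inversion: per angle, ramp filtering in frequency
space on a 4× zero-padded profile (apodizations: ram-lak, shepp-logan, hann),
back projection with linear (or nearest) interpolation, quadrature weight
π/N_φ and the 1/(2π) of the inversion formula.  On a smooth centered phantom
at 200 angles the self-consistency error against the package's own projector
is below 1%.

## Synthetic phantoms

The default phantom emulates typical photoacoustic targets: a vascular
skeleton of random smooth cubic-spline curves rasterized to one-voxel width
at pressure exactly 1; two ellipsoids of sub-unit pressure (defaults 0.3 and
0.6) emulating tumor-like blobs; and a linear ramp (default 0 → 0.8)
emulating tissue background — composed additively on an inner grid
(default 128×128×40) and embedded centered in a larger zero reconstruction
domain (default 281×281×40).  The curve generator replaces an unavailable
skeletonized vessel data set; it reproduces the statistical character (thin
bright curvilinear structures over smooth background) but not any specific
vasculature, so image-fidelity numbers are not comparable against published
values for real vessel data.  A second family (thin closed loops plus small
spheres, value 1) emulates hair-loop/microsphere calibration samples.

What the synthetic experiments do not model: optical scattering and
fluence variation (pressure is taken proportional to absorption), acoustic
attenuation and heterogeneous sound speed, the camera's limited view, and
detector/shot noise beyond additive white Gaussian noise on the snapshots.

## Scaled study conditions

The few-angle comparison in the test suite runs at desk scale: a structured
64×64×8 phantom (skeleton curves, two ellipsoids, a ramp), 96 uniform angles
versus an 8× subsampled 12, snapshot time c_s·T = 1 (the physical delay of
the experimental setup is of the order of the imaging volume's side length)
on a generously padded camera grid.  The data weight follows the 1/N_φ law
(μ = 1000 at 96 angles, 8000 at 12), and the iteration count follows the
convergence protocol of the full-size study — chosen so that further
iterations change the image insignificantly, and doubled for the few-angle
datum whose larger μ converges slower (N = 2000 / 4000).  Quality metrics
are PSNR (peak from the ground-truth maximum) and mean slice-wise SSIM with
a 7×7 window (a 3D-window variant is available).  Behavior asserted by the
acceptance tests: FBP collapses at 12 angles (streaks; SSIM drop ≥ 0.2)
while TGV degrades mildly (drop < 0.05); the true-zero background of the TGV
reconstruction is quieter than FBP's; and on the ramp the TV solution
clusters into plateaus (measured as the fraction of adjacent voxel pairs
along the ramp axis with near-identical values) where TGV stays smooth.

At these sizes the angular Nyquist relation Λ_min = Δφ·SL/90° puts one-voxel
skeleton curves beyond the resolvable scale at 12 angles, so thin structures
lose brightness in *all* methods — the same caveat the full-size study
reports for its few-angle reconstructions.

## Known limitations

- Second-order TGV only; no anisotropic voxel-aware derivatives (differences
  are taken in voxel units even when Δz ≠ Δx).
- Parallel-beam geometry only; no fan/cone beam.
- The projector's footprint model assumes pixels aligned with the grid; no
  supersampling of sub-pixel detector offsets.
- No preconditioned or accelerated primal-dual variants; runtime on large
  grids is dominated by the sparse projector products.
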