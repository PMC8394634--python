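# epdm-ct — CT reconstruction by extended power-divergence minimization

`epdm-ct` is a Python package for iterative tomographic image
reconstruction driven by a two-parameter family of divergences between the
measured and forward projections. It is aimed at people studying iterative
reconstruction algorithms — their objective functions, convergence behavior
and noise robustness — on simulated parallel-beam CT data.

## The model

Reconstruction solves `y = A x + δ` for a nonnegative image `x`, where `y`
is the sinogram (stacked line integrals), `A` the sparse ray/pixel
intersection-length operator, and `δ` measurement noise. The objective is
the extended power-divergence

```
Φ_{γ,α}(p, q) = Σ_i ∫_{p_i}^{q_i} (s^γ − p_i^γ) / s^{γα} ds ,   γ > 0, α ≥ 0,
```

applied as `V(x) = Φ_{γ,α}(y, Ax)`. The family connects the generalized
Kullback–Leibler divergence (γ, α) = (1, 1), half the squared L2 distance
(1, 0), the reverse-KL member (1, 2), Neyman's χ² (2, 1) and the
generalized Hellinger distances. The minimizing iteration is multiplicative,

```
z_j(n+1) = z_j(n) · f_j(z(n))^h ,
f_j(w) = [Σ_i A_ij y_i^γ (A_i w)^(−γα)] / [Σ_i A_ij (A_i w)^(γ(1−α))] ,
```

which for (γ, α) = (1, 1), h = 1 is exactly classical MLEM. The iteration
is the multiplicative-Euler discretization of the flow
`dx_j/dt = x_j log f_j(x)`, for which `V` is a Lyapunov function: on
consistent data (`y = Ae`) the true image `e` is an asymptotically stable
equilibrium and `V` never increases along trajectories. The package
implements the divergence (closed forms plus a quadrature oracle), the
iteration, the continuous-time system, a parallel-beam simulator
(modified Shepp–Logan phantom, exact Siddon-style projector, Gaussian
sinogram noise at a stated SNR), an FBP baseline, image metrics
(unnormalized `E(z) = ||e − z||₂`, SSIM, line profiles) and a config-driven
experiment harness.

## Worked example

The packaged benchmark protocol — 128×128 phantom, 180 views × 184 bins
(33,120 rays), 30 dB white Gaussian noise, h = 1, constant start — compares
MLEM against the divergence parameters matched to each checkpoint:

```python
from epdmct.experiments import ExperimentConfig, run_experiment
report = run_experiment(ExperimentConfig(seed=0))
print(report.summary())
```

prints

```
E(z(N))
     MLEM  PDEM(0.8, 1.2)  PDEM(0.5, 1.2)  PDEM(0.3, 1.2)
N
50   6.05            6.26             NaN             NaN
100  5.79             NaN            5.72             NaN
200  6.60             NaN             NaN            5.46

SSIM
     MLEM  PDEM(0.8, 1.2)  PDEM(0.5, 1.2)  PDEM(0.3, 1.2)
N
50  0.683           0.709             NaN             NaN
100 0.625             NaN           0.730             NaN
200 0.588             NaN             NaN           0.751
```

Read it as follows. `E` is the unnormalized L2 distance to the true
phantom (≈ 0.05 per-pixel RMS at E ≈ 6.4 for 16,384 pixels); SSIM is the
standard perceptual similarity (1 = identical). MLEM *semiconverges* on
noisy data: its E bottoms out near iteration 80 and rises again (6.60 at
n = 200 after 5.8 at n = 100), while a small γ with α > 1 keeps improving —
at n = 200 the (0.3, 1.2) member reaches E = 5.46 and SSIM 0.751 versus
MLEM's 6.60 / 0.588. On noise-free data every member decreases E
monotonically, and larger (γ, α) such as (1.3, 1.2) converge faster than
MLEM. Each column is populated only at its matched checkpoint (NaN
elsewhere).

The same protocol is available from the shell:

```
epdm-ct simulate --image-size 128 --snr-db 30 --seed 1 --out sim/
epdm-ct reconstruct --sinogram sim/sinogram_noisy.npy --geometry geom.yaml \
    --gamma 0.3 --alpha 1.2 --iters 200 --out rec/
epdm-ct experiment --config exp.yaml --out out/
epdm-ct sweep --config sweep.yaml --out sweep/
```

sklearn-style estimators (`PDEMReconstructor`, `MLEMReconstructor`,
`FBPReconstructor` with `fit` / fitted `image_`, `trace_`) wrap the same
functional core and compose with sklearn tooling.

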