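# fbfdeblur

Restoration of grayscale images — chest-CT slices being the motivating case —
that have been degraded by a *known* linear motion blur and additive noise.
The observation model is

    y = D x + η,

where `x` is the original image, `D` is 2-D convolution with a normalized
motion point-spread function (PSF), and `η` is Gaussian or Poisson noise.
Because deconvolution is ill-posed, the restoration is posed as regularized
least squares,

    min_x  ½‖Dx − y‖² + μ·g(x),

with `g` either the elementwise l1 norm or the Euclidean norm. A minimizer is
a zero of the monotone inclusion `0 ∈ ∇f(x) + μ∂g(x)` with
`∇f(x) = Dᵀ(Dx − y)`, which the package solves with Tseng's
forward-backward-forward (FBF) splitting:

    w_k     = prox_{λμg}(x_k − λ∇f(x_k))          (forward, backward)
    x_{k+1} = w_k − λ(∇f(w_k) − ∇f(x_k))          (forward correction)

starting from `x_0 = y`, with reference parameters λ = 0.001, μ = 0.3. The
correction step makes the iteration convergent — and Fejér monotone with
respect to the solution set — for any step λ < 1/L, L = ‖D‖², without the
cocoercivity assumption plain forward-backward needs.

The package provides, as both a library and a CLI:

- **Degradation simulation** — anti-aliased motion-PSF rasterization, FFT
  (circular) or reflect-boundary convolution with *exact* adjoints, seeded
  Gaussian/Poisson noise.
- **The FBF solver** — prox operators (soft- and block-thresholding),
  objective/gradient evaluation, divergence detection, per-iteration traces.
- **Quality metrics** — global-statistics SSIM, ISNR and SNR in dB.
- **Phantoms** — procedural chest-like, Shepp-Logan-like, sparse-spot and
  flat test images, so everything runs without any data download.
- **Estimators** — `MotionBlurDegrader` and `TsengDeconvolver` follow
  scikit-learn conventions (`get_params`/`set_params`/`fit`/`transform`) and
  compose in a `Pipeline`.

## Worked example

```python
import fbfdeblur as fbf

clean = fbf.generate_phantom(fbf.PhantomSpec(size=128, kind="chest", seed=7))
obs = fbf.degrade(clean, fbf.DegradationSpec(
    psf_length=30, psf_angle=60, noise_family="gaussian",
    noise_level=0.001, seed=7))
result = fbf.tseng_solve(
    fbf.RestorationProblem(obs),
    fbf.SolverConfig(regularizer="euclidean_norm"))  # λ=0.001, μ=0.3, 500 iters

print(f"SSIM degraded  {fbf.ssim(clean, obs.observed):.4f}")
print(f"SSIM restored  {fbf.ssim(clean, result.restored):.4f}")
print(f"ISNR           {fbf.isnr(clean, obs.observed, result.restored):+.4f} dB")
print(f"SNR            {fbf.snr(clean, result.restored):.2f} dB")
```

prints

```
SSIM degraded  0.7324
SSIM restored  0.7524
ISNR           +0.2223 dB
SNR            6.32 dB
```

SSIM = 1 would be perfect structural agreement; ISNR > 0 means the restored
image is closer to the clean image (in squared error) than the blurred,
noisy observation was, here by +0.22 dB after 500 iterations. Longer budgets
keep improving the result (≈ +3 dB ISNR and SSIM ≈ 0.89 at 30 000
iterations for this configuration). The same experiment from the shell:

```sh
fbfdeblur demo --size 128 --seed 7 --out demo_out
```

writes clean/degraded/restored PNGs, the PSF as a text matrix, a
per-iteration trace CSV, a metrics CSV and a reproducibility manifest for
both noise families.

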