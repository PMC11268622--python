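# Methods

## Observation model

A degraded image is modelled as `y = Dx + η` on [0, 1]-scaled intensities:

- `D` — 2-D convolution with a normalized linear-motion PSF. The PSF of
  length `L` pixels and direction `θ` (degrees counter-clockwise from
  horizontal, reduced mod 180) is defined intrinsically as the exact
  area-weighted rasterization of an `L × 1`-pixel rectangle rotated by `θ`:
  each kernel cell receives the area of its intersection with the rectangle
  (computed by polygon clipping), and the kernel is normalized to unit sum.
  `L = 1` is zero-extent motion and yields the 1×1 identity kernel. This
  definition is anti-aliased by construction, has minimal odd-sized support
  (zero-area border rows/columns are trimmed), and is checked in the tests
  against an independent supersampling rasterizer. It is *not* a
  bit-replication of any particular toolbox's built-in motion kernel and
  does not aim to be.
- `η` — either Gaussian noise, with `noise_level` interpreted as the
  **variance** on [0, 1] intensities (default 0.001), or Poisson noise with
  `noise_level` a scaling factor `s` (default 0.05): intensities are divided
  by `s`, Poisson-sampled and multiplied back, so the noise variance at
  intensity `x` is `s·x` and smaller `s` means less noise. Each degradation
  carries one explicit integer seed; there is no global random state.
  Degraded intensities are deliberately **not** clipped to [0, 1] — clipping
  would alter the additive model — and are only clipped at image export.

### Boundary handling and adjoints

The paperless question of what happens at the image border is resolved by
offering two modes and making the adjoint exact in both, because the
solver's correctness (and its step-size bound) is stated in terms of `Dᵀ`:

- `circular` (default): periodic convolution, diagonalized by the DFT. The
  forward map multiplies the spectrum by the optical transfer function
  (OTF), the adjoint by its conjugate. The operator norm is `max |OTF|`,
  which for a nonnegative unit-sum kernel is exactly 1 (attained at zero
  frequency), so `L = ‖D‖² ≤ 1`.
- `reflect`: reflect-pad, convolve, restrict. The adjoint is the exact
  transpose of that composition — full correlation followed by folding the
  pad contributions back onto their source pixels. Here `‖D‖` can slightly
  exceed 1 (border pixels are counted more than once by the padding), so the
  solver bounds it by deterministic power iteration with a small safety
  inflation.

The inner-product identity `⟨Du, v⟩ = ⟨u, Dᵀv⟩` is enforced to 1e-10 in the
tests for both modes, and forward/adjoint are additionally checked entry by
entry against dense matrices assembled independently.

## The solver

The restoration objective is `F(x) = ½‖Dx − y‖² + μ·g(x)` with
`g(x) = ‖x‖₁` (elementwise, default) or `g(x) = ‖x‖₂`. Its minimizers are
the zeros of the monotone inclusion `0 ∈ ∇f(x) + μ∂g(x)`,
`∇f(x) = Dᵀ(Dx − y)`. One iteration of the forward-backward-forward
splitting is

    w_k     = prox_{λμg}(x_k − λ∇f(x_k))
    x_{k+1} = w_k − λ(∇f(w_k) − ∇f(x_k)),

two gradient evaluations and one prox per step. `prox` is soft-thresholding
for l1 and block shrinkage (`v·max(1 − t/‖v‖, 0)`) for the Euclidean norm.

Parameters, defaults, and why:

| parameter | default | meaning |
|---|---|---|
| `step_size` (λ) | 0.001 | step; must satisfy λ·L < 1, asserted at solve time from the OTF/power-iteration bound on L = ‖D‖². The reference value 0.001 is far inside the stable range (L ≤ 1 circular). |
| `reg_weight` (μ) | 0.3 | regularization weight on [0, 1] intensities (reference value). |
| `regularizer` | `l1` | which `g`; see the discussion below. |
| `max_iters` | 500 | iteration cap; the reference iteration has no stopping rule of its own. |
| `rel_tol` | 1e-6 | stop when `‖x_{k+1} − x_k‖ / max(‖x_k‖, 1e-12)` drops below this; the 1e-12 floor guards all-zero iterates. |

`x_0` defaults to the observed image. Iterates are unconstrained reals (the
objective has no box constraint); export clips. The solver is fully
deterministic, records objective and step norm per iteration (optionally
the iterates and per-iteration SSIM/ISNR), and aborts with a diagnostic
error if the objective exceeds 10× its running minimum — impossible for a
valid step size, and in practice a step-size misconfiguration detector.

### Which regularizer?

The objective is stated with `g = ‖x‖₁`, but the subdifferential the
reference algorithm actually plugs into its resolvent,
`∂g(x) = x/‖x‖ (x ≠ 0)`, is that of the **Euclidean** norm. The two give
very different behaviour at μ = 0.3 on [0, 1] intensities:

- **l1**: at stationarity `Dᵀ(y − Dx) = μ·sign(x)` on the support, so in
  plateau regions (where `D` acts nearly as the identity) the solution sits
  about μ ≈ 0.3 *below* the data — a large systematic bias for images whose
  full dynamic range is 1. The l1 reading of the reference weight therefore
  over-shrinks, and quality metrics degrade as the iterate approaches the
  minimizer.
- **Euclidean norm**: the effective shrinkage per step is `λμ/‖x‖`, which
  for a whole image (‖x‖ ≫ μ) is negligible; the iteration behaves as a
  convergent gradient descent on the data-fit term and genuinely
  deconvolves, with early stopping providing the regularization
  (semiconvergence).

Both variants are first-class. The solver default stays `l1`, matching the
written objective; the end-to-end experiment protocol (the `demo`
subcommand and the end-to-end acceptance test) uses `euclidean_norm`,
matching the literal resolvent, because that is the variant under which the
reference protocol (λ = 0.001, μ = 0.3, x₀ = y) actually improves the
degraded image — as the end-to-end tests verify for both noise families
across seeds. For genuine sparse recovery with the l1 model, μ should be
chosen orders of magnitude smaller than 0.3 (the solver-vs-reference tests
use μ = 0.05 on random images with a short blur).

### Convergence checks

Theory says the FBF iterates with λ < 1/L are Fejér monotone: they never
move farther from any solution. The tests verify this empirically —
`‖x_{k+1} − x*‖ ≤ ‖x_k − x*‖ + 1e-12` for every iteration on five small
problems, with `x*` taken from a 10⁵-iteration independent dense
proximal-gradient (ISTA) reference — and verify that the final objective
agrees with the ISTA reference to 1e-4 relative on twenty random 16×16
problems. Converged solutions are also checked against the fixed-point
optimality residual `‖x − prox_{λμg}(x − λ∇f(x))‖/λ ≤ 1e-6`.

## Metrics

- **SSIM** (global form): with means `μx, μy`, population variances
  `σx², σy²` and covariance `σxy` over the *whole* image,
  `SSIM = (2μxμy + c₁)(2σxy + c₂) / ((μx² + μy² + c₁)(σx² + σy² + c₂))`,
  `c₁ = (0.01R)²`, `c₂ = (0.03R)²`, dynamic range R = 1. Global statistics
  are the package's primary definition; the usual sliding-window mean SSIM
  is available via `windowed=True` (scikit-image). Population (divide-by-N)
  convention throughout. `ssim(x, x) = 1` holds exactly in floating point
  because numerator and denominator are the same expression when the inputs
  are identical.
- **ISNR** `= 10·log₁₀(‖x − y‖²/‖x − x̂‖²)` and **SNR**
  `= 10·log₁₀(‖x‖²/‖x − x̂‖²)`, both in dB with ratios of sums of squares
  (the standard convention). A perfect estimate yields +∞ rather than an
  exception; an all-zero clean image makes SNR undefined and is rejected.

## Phantoms

Procedural, deterministic per seed, rendered at 4× supersampling and
block-averaged so shape edges are anti-aliased and do not masquerade as
blur artifacts:

- `chest` — air background 0, lung fields 0.15, soft tissue 0.5, bony shell
  / vertebra / aorta-like disc 0.9: the gross contrast layout of an axial
  chest-CT slice, with ≥ 0.2 contrast between tissue plateaus so
  restoration effects are measurable. Not anatomically accurate and not
  intended to be.
- `shepp_like` — a head-phantom-style composition of nested ellipses.
- `sparse_spots` — `n_spots` non-overlapping bright discs (radius 2.5 px)
  on a zero background, capped at 5% pixel occupancy; the favorable regime
  for the l1 model.
- `flat` — constant 0.5; degenerate-input testing.

`contrast_jitter` perturbs plateau intensities uniformly (seeded) for
robustness studies. What phantoms do **not** emulate: CT acquisition
physics (Hounsfield calibration, beam hardening, streaks), anatomical
texture, or the specific thoracic-disease presentations of real archive CT
images. Passing tests therefore demonstrate correctness of the operators,
solver and metrics, and that the method restores piecewise-smooth
high-contrast images under the stated degradation — not clinical
performance on real CT data.

## Numerical choices

- PSF cells with intersection area < 1e-12 are treated as outside the
  support; kernels must sum to 1 within 1e-12.
- Circular convolution uses the real FFT; roundoff is well below the 1e-10
  adjoint tolerance at the image sizes involved.
- Soft-thresholding at threshold 0 is the exact identity; block shrinkage
  returns exact zero when `‖v‖ ≤ t` (no division by a tiny norm).
- Test problem sizes: operator oracles on 8×8 against dense matrices;
  solver-vs-reference on 16×16 with a 3×3 kernel; Fejér on 4×4–7×7; the
  end-to-end protocol on 128×128 phantoms with the length-30 kernel.

## Limitations

- Blur must be known (non-blind) and spatially invariant; grayscale 2-D
  only.
- The Poisson `noise_level` parameterization is one reasonable reading of a
  "scaling factor"; other toolboxes parameterize Poisson noise differently.
- Global SSIM can mask local structural errors; use `windowed=True` when
  locality matters.
- No line search, inertia or relaxation; λ is fixed, so long blurs need
  many iterations at the reference step size.
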