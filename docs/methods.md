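# Methods

## Noise model

Magnitude signals are modelled as Rician: `M = √((A+n_R)² + n_I²)` with
`n_R, n_I ~ N(0, σ²)` independent — the distribution of a single complex
image's magnitude after sum-of-squares reconstruction. SNR is defined as
`1/σ` referenced to a unit-amplitude `b = 0` signal; *effective* SNR at a
given b-value is lower by the signal attenuation. σ is treated as a single
scalar, constant across voxels for a given dataset. Spatially varying noise
maps and noncentral-chi statistics (multi-coil GRAPPA magnitudes) are out of
scope.

The simulator draws noise exactly this way (two Gaussian channels, then
magnitude), never from a Rician random generator, so the construction itself
is exercised; tests pin the Rayleigh limit of its mean (`σ√(π/2)`) and
variance (`σ²(2 − π/2)`) and the closed-form mean
`E[M] = σ√(π/2)·L½(−A²/2σ²)` by Monte Carlo.

## Losses and their numerics

Two amortised batch objectives compare measured signals `M` (N voxels × Nz
measurements) with model predictions `Â`:

- `mse_loss` — `(1/N)Σ_j (1/Nz)Σ_i (M−Â)²`; its minimiser is the
  least-squares signal, an unbiased estimate of `E[M]`, which exceeds the
  noise-free signal under Rician noise.
- `nlr_loss` — `(1/N)Σ_j [−Σ_i log p(M|Â,σ)]`, the negative log Rician
  likelihood; its minimiser is the maximum-likelihood signal.

`log I₀` is computed as `log(i0e(x)) + x` with SciPy's exponentially scaled
Bessel (the Cephes two-range Chebyshev approximation). `I₀e` is bounded on
`[0, ∞)`, so neither the loss nor its gradient — which needs only the
bounded ratio `I₁/I₀ = i1e/i0e ∈ [0, 1)` — can overflow at any SNR. A
1000-term power-series evaluation of `log I₀`, accumulated in the log domain
(`gammaln` + `logsumexp`) with an explicit convergence check, serves as the
independent ground truth in tests and in the accuracy scan; it is never used
inside a loss. `expected_magnitude` evaluates the Laguerre polynomial
through the scaled-Bessel identity
`L½(−t) = (1+t)·i0e(t/2) + t·i1e(t/2)`, which is stable for arbitrarily
large `t`; tests cross-check it against `hyp1f1` and Monte Carlo.

Losses accumulate in double precision. Predictions are floored at `1e-12`
inside the losses only, so an optimiser that transiently proposes a
non-positive signal cannot leave the Bessel domain.

## Forward model and units

IVIM: `Â(b) = S0·(f·e^{−b(Dp+Dt)} + (1−f)·e^{−b·Dt})`. Units are fixed
package-wide at `b` in ms/μm² and diffusivities in μm²/ms, so `b·D` is
dimensionless and `Dt` (0.4–3) has the same magnitude as `S0` (~1) — this
keeps backpropagation steps comparably sized across parameters. The default
protocol is the ten-b-value clinical set 0, 0.01, 0.02, 0.03, 0.05, 0.08,
0.1, 0.2, 0.4, 0.8 ms/μm² (0–800 s/mm²); FSL-style b-value files in s/mm²
are converted (÷1000) at I/O time.

## Simulation design

Ground-truth parameters form a full factorial grid of equidistant levels
(default 10 per parameter) over Dt ∈ [0.4, 3] μm²/ms, Dp ∈ [10, 150] μm²/ms,
f ∈ [0.1, 0.5], S0 ∈ [0.8, 1.2] — 10⁴ combinations; a wider S0 preset
([0.1, 1]) mirrors body imaging where unweighted signals vary more. Study
SNRs are {30, 20, 10, 7.5, 5}, varied through σ only. Each combination gets
a fixed number of independent noise instantiations (20 at full scale →
200,000 voxels). Validation voxels (default 1000) are grid combinations
sampled uniformly with fresh noise. One parent seed spawns independent
child streams per split, so resizing one split never perturbs another.

What the generator does **not** emulate: spatial structure and partial
volume, anatomy-dependent parameter correlations, scanner drift, motion,
preprocessing-induced noise correlations, and spatially varying σ. Passing
tests therefore demonstrate estimator behaviour under the idealised noise
model, not performance on real acquisitions.

## Network and training

The encoder is a fully connected net — input width Nz, three hidden ELU
layers of width Nz, four outputs — and the decoder is the fixed IVIM model,
so training needs no parameter labels. Raw outputs map to parameters through
a sigmoid scaled to per-parameter ranges. **Output ranges** default to the
simulation ranges widened by half the span on each side (Dt ≈ [0.001, 4.3],
Dp ≈ [0.001, 220], f [0, 0.7], S0 [0.6, 1.4]): at SNR 10 the voxel-wise ML
estimator of Dt has a sampling standard deviation of ≈0.45 μm²/ms at
Dt = 3, so a tight transform clips the upper tail and manufactures edge
bias (we measured +20% at the lowest and −9 percentage points extra at the
highest Dt level with 10%-widened ranges), which would be an artifact of the
head, not of the loss being studied. The widening fraction is an API
parameter.

Optimisation follows the standard recipe: Adam (lr 1e-3, betas (0.9, 0.999),
weight decay 0), batch size 256, reshuffled batches with the last partial
batch kept, early stopping when the validation loss sets no new strict
minimum for 50 consecutive epochs (final weights kept), 300-epoch cap at
full scale. A *common initialisation* protocol trains several NLR networks
from different seeds and keeps the state with the lowest validation loss, so
MSE/NLR comparisons share their starting point bit-exactly. Weights
initialise as `U(±1/√fan_in)`. Every loss and gradient evaluation is checked
for finiteness; a non-finite value aborts with epoch/batch/σ diagnostics.

Because the network is tiny (374 weights at Nz = 10) the whole stack runs on
NumPy arrays in float64 with analytic backpropagation through the decoder
jacobian; training is bit-deterministic given the seed. For small,
effectively noiseless datasets, minibatch Adam stalls orders of magnitude
above the attainable optimum, which matters when the weakly identified Dp
must be resolved to a few percent; `network.refine()` therefore offers
deterministic full-batch L-BFGS fine-tuning of the weights.

A `sigma_scale` factor (useful range 0.5–2) multiplies σ inside the NLR loss
and the NLR fitting objective to study misestimation: overestimating σ
inflates diffusivity estimates; underestimation moves NLR behaviour toward
MSE.

## Conventional fitting

`fit_voxel` runs bounded L-BFGS-B with analytic gradients on either
objective; bounds default to the same widened ranges as the network head.
The objective is non-convex (local minima are a known feature of IVIM
fitting), so `fit_volume` supports seeded multistart (default 3: bounds
midpoint plus uniform draws) and reports per-voxel convergence flags rather
than raising. Tolerances are set tight (`ftol` 1e-15) because the objective
is cheap and noiseless identifiability checks need near-zero residuals.

## Evaluation conventions

Errors are estimate − truth, reduced per ground-truth combination to bias
(mean error), std (population, ddof = 0), RMSE, median and IQR. Population
std is used so `rmse² = bias² + std²` holds exactly; the identity is
asserted on every emitted table. Quartiles use linear interpolation
(type 7). Marginal summaries reduce combination-level metrics to one row per
ground-truth level of a chosen parameter (mean ± sd across the other
parameters' combinations). Boxplot five-number summaries place whiskers at
the most extreme point within 1.5·IQR *of the median* — the convention of
the study's error plots — with the standard Tukey rule (from the quartiles)
behind a flag.

## Noise estimation

In signal-free background regions the Rician reduces to Rayleigh with mean
`σ√(π/2)`, giving the unbiased estimator `σ̂ = mean(M_bg)/√(π/2)` (default
sample size 10,000). Background voxels are supplied explicitly (value list
or volume + mask); exactly-zero magnitudes (integer quantisation) are
excluded with a logged count. No automatic background detection is
attempted.

## Reduced problem sizes

The bundled study pipeline (`reduced_bias_study`, used by the test suite and
`scripts/acceptance.py`) keeps the full 10⁴-combination grid but uses 5
noise instantiations per combination for training (50,000 voxels), best-of-4
common initialisation at 50 epochs, and a 100-epoch production run — about
one minute per SNR on a single CPU. The test set keeps the full 20
instantiations per combination (200,000 voxels; prediction is cheap), so
per-level bias estimates carry ≈0.3 percentage points of standard error.
At these sizes the MSE-trained network's top-level Dt bias at SNR 10 is
within ~1 percentage point of its converged value (cross-checked against
fully converged voxel-wise least-squares fits of the same data, the
infinite-capacity limit of amortised MSE training).

## Known limitations

- Scalar σ per dataset; no spatially varying noise, no noncentral-chi.
- The output-transform choice (sigmoid + widened ranges) is a design
  decision the underlying study design leaves open; it measurably shapes
  bias at the edges of the parameter ranges, which is why it is wide by
  default and exposed in the API.
- Residual NLR bias of a few percent at low SNR is expected: maximum
  likelihood is only asymptotically unbiased, and Nz = 10 measurements per
  voxel is far from asymptopia.
- Dp is weakly identified by low-b protocols; its error distributions are
  strongly right-skewed at low SNR, inflating mean-based bias summaries
  (median summaries are provided).
- The NIfTI pathway (4D volume → voxel table → parameter maps) is covered by
  synthetic round-trip tests; no real acquisitions ship with the package.
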