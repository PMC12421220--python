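# ricianfit

Numerically stable **negative log Rician likelihood (NLR) loss** for
quantitative MRI parameter estimation, demonstrated end to end on the
intravoxel incoherent motion (IVIM) diffusion model: Rician signal
simulation, self-supervised network training, conventional voxel-wise
fitting, noise estimation, and bias/precision evaluation.

## The problem

Quantitative MRI estimates tissue parameters by fitting a biophysical signal
model to magnitude images. Magnitude data from a single complex image follow
a **Rician** distribution: with noise-free signal `A` and per-channel noise
standard deviation `σ`,

    p(M | A, σ) = M/σ² · exp(−(M² + A²)/(2σ²)) · I₀(M·A/σ²)

whose mean `E[M] = σ·√(π/2)·L½(−A²/2σ²)` always exceeds `A`. Training
self-supervised networks (or fitting voxels) by **mean squared error**
therefore matches `E[M]`, not `A`, and systematically under-estimates decay
rates at low SNR. The remedy is maximum likelihood: minimise the negative
log Rician likelihood

    L_NLR = (1/N) Σ_j −Σ_i [ log(M/σ²) − (M² + Â²)/(2σ²) + log I₀(M·Â/σ²) ]

The catch is `log I₀(x)`: its argument scales like SNR² and `I₀` overflows
double precision near `x ≈ 713`. This package evaluates it through the
exponentially scaled Bessel function (`log I₀(x) = log I₀e(x) + x`, Cephes
Chebyshev approximation via `scipy.special.i0e`), which keeps the loss and
its gradient finite at any SNR.

The exemplar model is IVIM: `Â(b) = S0·(f·e^{−b(Dp+Dt)} + (1−f)·e^{−b·Dt})`
with tissue diffusivity `Dt` [μm²/ms], pseudo-diffusion `Dp` [μm²/ms],
perfusion fraction `f`, and unweighted signal `S0`; `b` in ms/μm²
(1 ms/μm² = 1000 s/mm²).

## Worked example

`examples/conventional_fitting.py` fits 648 simulated voxels at SNR 5 with
both objectives:

```
fitting 648 voxels twice (NLR and LSQ objectives)
NLR: Dt bias +0.1337 um^2/ms | Dt std 1.1881 | converged 78%
LSQ: Dt bias -0.5989 um^2/ms | Dt std 1.1212 | converged 97%

sigma estimated from 10,000 background voxels: 0.2014 (true 0.2) -> SNR 5.0
```

Least squares under-estimates `Dt` by ~0.6 μm²/ms on average at this noise
level because it chases the inflated Rician mean; the likelihood objective
removes most of that systematic error at the cost of a slightly wider error
spread — the central accuracy/precision trade-off between the two losses.
The last line shows the Rayleigh-mean estimator `σ̂ = mean(M_bg)/√(π/2)`
recovering the noise level from background voxels.

The other examples, one capability each:

- `examples/loss_basics.py` — why MSE prefers an inflated signal under
  Rician noise and NLR does not (20,000 copies of one voxel).
- `examples/stable_log_bessel.py` — naive `log(i0(x))` overflows at
  `x = 1600` (the SNR-40 regime) while `log_i0` matches the 1000-term
  series ground truth to 1e-9 up to SNR 40.
- `examples/train_self_supervised.py` — train the encoder with the NLR loss
  at SNR 10 and inspect Dt recovery per ground-truth level (~15 s).
- `examples/bias_study.py` — the full reduced-scale study: common
  initialisation, MSE vs NLR training, 200,000-voxel evaluation (~1 min).

A thin CLI wraps the same functions for shell pipelines:

```sh
ricianfit simulate --snr 10 --seed 1 --n-levels 4 --reps-per-combo 5 --out data/
ricianfit train    --data data/ --loss NLR --out model/
ricianfit predict  --model model/ --data data/train.csv --out pred/
ricianfit evaluate --estimates pred/params.csv --test data/train.csv --out eval/
ricianfit fit      --data data/train.csv --objective NLR --sigma 0.1 --out fits/
ricianfit estimate-sigma --values background.txt --out sigma/
```

Every output directory receives a `manifest.json` snapshot (command, config,
seeds, σ, protocol, versions) so results are traceable.

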