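"""Voxel-wise maximum-likelihood versus least-squares IVIM fitting.

Fits each simulated voxel separately with the Rician-likelihood (NLR) and
least-squares (LSQ) objectives at SNR 5 and compares accuracy and precision
of the tissue diffusivity. Demonstrates the bias-precision trade-off without
any neural network. Takes ~20 s.
"""

import numpy as np

import ricianfit as rf

protocol = rf.AcquisitionProtocol.default()
sigma = 0.2  # SNR 5

grid = rf.make_parameter_grid(n_levels=3)
batch, _ = rf.build_dataset(grid, protocol, sigma, reps_per_combo=8,
                            seed=3, n_validation=0)
print(f"fitting {batch.n_voxels} voxels twice (NLR and LSQ objectives)")

for objective, sig in (("NLR", sigma), ("LSQ", None)):
    fits = rf.fit_volume(batch, objective=objective, sigma=sig,
                         multistart=1, seed=1)
    err = rf.error_table(fits, batch.truth)
    print(f"{objective}: Dt bias {err['err_Dt'].mean():+7.4f} um^2/ms | "
          f"Dt std {err['err_Dt'].std():6.4f} | "
          f"converged {fits['converged'].mean():.0%}")

print()
print("The likelihood objective trades a little precision (larger std) for")
print("much smaller systematic error, because least squares matches the")
print("Rician mean E[M], which lies above the noise-free signal.")

spec = rf.estimate_sigma(
    rf.add_rician_noise(np.zeros(10_000), sigma, seed=9))
print(f"\nsigma estimated from 10,000 background voxels: "
      f"{spec.sigma:.4f} (true {sigma}) -> SNR {spec.snr:.1f}")
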