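"""Reduced-scale reproduction of the loss-comparison study at SNR 10.

Runs the full pipeline — factorial simulation grid, common initialisation,
MSE and NLR training, evaluation on 200,000 unseen voxels — and prints the
mean relative Dt bias per ground-truth level for both losses.
Takes ~1 minute on one CPU.
"""

import numpy as np

import ricianfit as rf

study = rf.reduced_bias_study(snr=10.0, seed=1)
levels = study["dt_levels"]

print(f"trained on {study['n_train']} voxels, tested on {study['n_test']} "
      f"unseen voxels at SNR {study['snr']:g}\n")
print(f"{'true Dt':>8} {'MSE bias %':>11} {'NLR bias %':>11}")
mse = study["per_loss"]["MSE"]["dt_level_bias_percent"]
nlr = study["per_loss"]["NLR"]["dt_level_bias_percent"]
for lev, b_mse, b_nlr in zip(levels, mse, nlr):
    print(f"{lev:8.2f} {b_mse:+11.1f} {b_nlr:+11.1f}")

print()
print(f"MSE loss: Dt bias at the highest diffusivity reaches "
      f"{mse[-1]:+.1f} % (effective SNR is lowest there).")
print(f"NLR loss: the worst level stays at "
      f"{nlr[np.argmax(np.abs(nlr))]:+.1f} % — the likelihood model absorbs "
      f"the Rician shift.")
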