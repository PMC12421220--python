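"""Train a small self-supervised network on simulated IVIM data.

Simulates Rician-noise signals on a reduced parameter grid at SNR 10, trains
the encoder (the IVIM model is the fixed decoder) with the NLR loss, and
reports how well the tissue diffusivity Dt is recovered on unseen data.
Takes ~15 s.
"""

import numpy as np

import ricianfit as rf

protocol = rf.AcquisitionProtocol.default()
snr = 10.0
sigma = 1.0 / snr

grid = rf.make_parameter_grid(n_levels=6)  # 1296 parameter combinations
train_data, val_data = rf.build_dataset(grid, protocol, sigma,
                                        reps_per_combo=20, seed=1,
                                        n_validation=500)
test_data, _ = rf.build_dataset(grid, protocol, sigma, reps_per_combo=10,
                                seed=2, n_validation=0)
print(f"training on {train_data.n_voxels} voxels at SNR {snr:g}")

net = rf.build_network(rf.NetworkConfig(n_inputs=protocol.n_measurements),
                       protocol, seed=1)
config = rf.TrainingConfig(loss="NLR", sigma=sigma, max_epochs=100,
                           patience=50, seed=1)
history = rf.train(net, train_data, val_data, config)
print(f"trained {history['epochs_run']} epochs; validation loss "
      f"{history['val_loss'][0]:.3f} -> {history['val_loss'][-1]:.3f}")

estimates, _ = rf.predict(net, test_data)
errors = rf.error_table(estimates, test_data.truth)
bias_by_level = errors.groupby("true_Dt")["rel_Dt"].mean() * 100

print()
print("mean relative Dt error (%) by ground-truth Dt level:")
for level, bias in bias_by_level.items():
    print(f"  Dt = {level:4.2f} um^2/ms : {bias:+6.1f} %")
print()
print("Residual bias concentrates at the grid edges (skewed estimator")
print("sampling distributions at SNR 10). A network trained with the MSE")
print("loss instead shows a strong negative trend — Dt increasingly")
print("under-estimated as the decay steepens; see examples/bias_study.py")
print("for the full side-by-side comparison at production scale.")
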