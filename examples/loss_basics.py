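"""Rician noise shifts magnitude signals upward; the NLR loss knows this.

Builds a noise-free IVIM decay, corrupts it with Rician noise at SNR 10, and
compares the two training objectives on the true signal versus an inflated
signal. The MSE prefers the inflated prediction (it chases E[M] > A), while
the negative log Rician likelihood is minimised near the true signal.
"""

import numpy as np

import ricianfit as rf

protocol = rf.AcquisitionProtocol.default()
params = rf.IVIMParams(Dt=1.5, Dp=50.0, f=0.2, S0=1.0)
sigma = 0.1  # SNR 10 at unit b=0 signal

A = rf.ivim_signal(params, protocol)
rng_voxels = 20_000  # many noisy copies of the same voxel
M = rf.add_rician_noise(np.tile(A, (rng_voxels, 1)), sigma, seed=0)

print("b (ms/um^2):       ", np.array(protocol.b_values))
print("noise-free signal: ", A.round(4))
print("mean magnitude:    ", M.mean(axis=0).round(4))
print("E[M] (closed form):", rf.expected_magnitude(A, sigma).round(4))
print()

truth = np.tile(A, (rng_voxels, 1))
inflated = np.tile(rf.expected_magnitude(A, sigma), (rng_voxels, 1))
for name, loss in (("MSE", lambda a: rf.mse_loss(M, a).value),
                   ("NLR", lambda a: rf.nlr_loss(M, a, sigma).value)):
    at_truth, at_inflated = loss(truth), loss(inflated)
    better = "TRUE signal" if at_truth < at_inflated else "INFLATED signal"
    print(f"{name} loss: at truth {at_truth:9.5f} | at E[M] "
          f"{at_inflated:9.5f}  -> prefers the {better}")

print()
print("The inflated prediction wins under MSE because the Rician mean sits")
print("above the noise-free signal, especially at high b where the signal")
print("is weak; a model fitted by least squares therefore under-estimates")
print("the decay rate Dt. The likelihood-based loss peaks at the true A.")
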