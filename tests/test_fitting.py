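"""Conventional voxel-wise fitting with NLR and LSQ objectives."""

import numpy as np
import pytest

import ricianfit as rf


@pytest.fixture
def truth_params():
    return np.array([1.2, 60.0, 0.25, 1.0])


class TestFitVoxel:
    def test_noise_free_lsq_from_truth_is_fixed_point(self, protocol,
                                                      truth_params):
        A = rf.ivim_signal(truth_params, protocol)
        res = rf.fit_voxel(A, protocol, objective="LSQ", init=truth_params)
        assert res.converged
        assert res.objective_value == pytest.approx(0.0, abs=1e-12)
        assert res.as_array() == pytest.approx(truth_params, rel=1e-6)

    def test_nlr_matches_coarse_to_fine_grid_oracle(self, protocol,
                                                    truth_params):
        # the objective has local minima, so the fit uses multistart and the
        # oracle is an independent 4-D coarse-to-fine grid search
        sigma = 0.1
        A = rf.ivim_signal(truth_params, protocol)
        M = rf.add_rician_noise(A, sigma, seed=0)
        batch = rf.SignalBatch(M=M[None, :], protocol=protocol)
        res = rf.fit_volume(batch, objective="NLR", sigma=sigma,
                            multistart=8, seed=2).iloc[0]

        bounds = rf.default_bounds()
        lo = np.array([bounds[n][0] for n in rf.PARAM_NAMES])
        hi = np.array([bounds[n][1] for n in rf.PARAM_NAMES])
        # three range-halving refinements: fine enough to pin the basin,
        # coarse enough that one grid step exceeds the wander of the
        # optimiser along the likelihood's flat valley
        best = None
        for _ in range(3):
            axes = [np.linspace(l, h, 9) for l, h in zip(lo, hi)]
            mesh = np.stack(np.meshgrid(*axes, indexing="ij"),
                            axis=-1).reshape(-1, 4)
            Ahat = rf.ivim_signal(mesh, protocol)
            obj = -np.sum(
                rf.rician_logpdf(M[None, :], np.maximum(Ahat, 1e-12), sigma),
                axis=1)
            k = int(np.argmin(obj))
            best = (obj[k], mesh[k])
            span = (hi - lo) / 4
            lo = np.maximum(lo, best[1] - span)
            hi = np.minimum(hi, best[1] + span)
        fine_step = (hi - lo) / 8
        assert res["objective_value"] <= best[0] + 1e-3
        est = np.array([res[n] for n in rf.PARAM_NAMES])
        assert np.all(np.abs(est - best[1]) <= fine_step + 1e-9)

    def test_nlr_and_lsq_agree_in_gaussian_limit(self, protocol,
                                                 truth_params):
        sigma = 0.01  # SNR 100
        M = rf.add_rician_noise(rf.ivim_signal(truth_params, protocol),
                                sigma, seed=6)
        nlr = rf.fit_voxel(M, protocol, objective="NLR", sigma=sigma)
        lsq = rf.fit_voxel(M, protocol, objective="LSQ")
        assert nlr.params["Dt"] == pytest.approx(lsq.params["Dt"], rel=0.01)

    def test_validation(self, protocol):
        M = np.full(10, 0.5)
        with pytest.raises(ValueError, match="sigma"):
            rf.fit_voxel(M, protocol, objective="NLR")
        with pytest.raises(ValueError, match="bounds"):
            rf.fit_voxel(M, protocol, objective="LSQ",
                         init=np.array([100.0, 50.0, 0.2, 1.0]))
        with pytest.raises(ValueError):
            rf.fit_voxel(M[:3], rf.AcquisitionProtocol([0.0, 0.1, 0.2]),
                         objective="LSQ")


class TestFitVolume:
    def test_empty_batch(self, protocol):
        batch = rf.SignalBatch(M=np.empty((0, 10)), protocol=protocol)
        out = rf.fit_volume(batch, objective="LSQ")
        assert len(out) == 0
        assert list(out.columns[:4]) == list(rf.PARAM_NAMES)

    def test_deterministic(self, small_noisy_batch):
        sub = rf.SignalBatch(M=small_noisy_batch.M[:10],
                             protocol=small_noisy_batch.protocol)
        a = rf.fit_volume(sub, objective="NLR", sigma=0.1, seed=3)
        b = rf.fit_volume(sub, objective="NLR", sigma=0.1, seed=3)
        assert a.equals(b)

    def test_multistart_never_worse(self, small_noisy_batch):
        sub = rf.SignalBatch(M=small_noisy_batch.M[:20],
                             protocol=small_noisy_batch.protocol)
        one = rf.fit_volume(sub, objective="NLR", sigma=0.1, multistart=1,
                            seed=3)
        five = rf.fit_volume(sub, objective="NLR", sigma=0.1, multistart=5,
                             seed=3)
        assert np.all(five["objective_value"].to_numpy()
                      <= one["objective_value"].to_numpy() + 1e-9)

    def test_noise_free_identifiability_both_objectives(self, protocol):
        grid = rf.make_parameter_grid(n_levels=2)
        batch, _ = rf.build_dataset(grid, protocol, sigma=1e-9,
                                    reps_per_combo=1, seed=2, n_validation=0)
        truth = batch.truth[list(rf.PARAM_NAMES)].to_numpy()
        for obj, sig in (("LSQ", None), ("NLR", 1e-9)):
            out = rf.fit_volume(batch, objective=obj, sigma=sig,
                                multistart=3, seed=1)
            est = out[list(rf.PARAM_NAMES)].to_numpy()
            assert np.allclose(est, truth, rtol=1e-3), obj


@pytest.fixture(scope="module")
def low_snr_fits(protocol):
    # SNR 5: strong Rician bias regime; moderate voxel count keeps the
    # suite fast while the mean inequality is a large effect
    grid = rf.make_parameter_grid(n_levels=3)
    reps = 2500 // len(grid) + 1
    batch, _ = rf.build_dataset(grid, protocol, sigma=0.2,
                                reps_per_combo=reps, seed=13,
                                n_validation=0)
    fits = {}
    for obj, sig in (("NLR", 0.2), ("LSQ", None)):
        fits[obj] = rf.fit_volume(batch, objective=obj, sigma=sig,
                                  multistart=1, seed=13)
    return batch, fits


class TestLossComparisonProperties:
    def test_nlr_predictions_sit_below_lsq_on_average(self, low_snr_fits,
                                                      protocol):
        # least squares matches E[M] > A, so its predicted signals exceed the
        # likelihood fit's on average
        batch, fits = low_snr_fits
        mean_pred = {
            obj: rf.ivim_signal(
                fits[obj][list(rf.PARAM_NAMES)].to_numpy(), protocol).mean()
            for obj in fits}
        assert mean_pred["NLR"] <= mean_pred["LSQ"]

    def test_bias_precision_tradeoff_for_dt(self, low_snr_fits):
        batch, fits = low_snr_fits
        stats = {}
        for obj, out in fits.items():
            err = rf.error_table(out, batch.truth)
            stats[obj] = (abs(err["err_Dt"].mean()), err["err_Dt"].std())
        assert stats["NLR"][0] < stats["LSQ"][0]   # lower |bias|
        assert stats["NLR"][1] >= stats["LSQ"][1]  # at no better precision

    def test_sigma_overestimation_inflates_diffusivity(self,
                                                       small_noisy_batch):
        sub = rf.SignalBatch(M=small_noisy_batch.M[:60],
                             protocol=small_noisy_batch.protocol)
        base = rf.fit_volume(sub, objective="NLR", sigma=0.1,
                             sigma_scale=1.0, multistart=1, seed=4)
        over = rf.fit_volume(sub, objective="NLR", sigma=0.1,
                             sigma_scale=2.0, multistart=1, seed=4)
        assert over["Dt"].mean() > base["Dt"].mean()
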