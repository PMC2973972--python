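"""PPI: eigenvariate, deconvolution, regressor construction, sign recovery."""

import numpy as np
import pandas as pd
import pytest

from stopsig import hemo
from stopsig.bold import RegionSpec, synthesize_bold, tile_region
from stopsig.glm import group_t
from stopsig.ppi import (
    DeconvolutionOperator,
    PPIModel,
    deconvolve,
    extract_eigenvariate,
    ppi_regressors,
    task_nuisance_regressors,
)
from stopsig.race import SubjectParams, simulate_session


class TestEigenvariate:
    def test_identical_voxels_return_standardized_series(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=200)
        V = np.tile(s, (10, 1))
        e = extract_eigenvariate(V).series
        z = (s - s.mean()) / s.std(ddof=1)
        assert np.allclose(e, z, atol=1e-8)

    def test_opposed_voxels_tie_break_is_deterministic(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=100)
        V = np.vstack([s, -s, s, -s])
        a = extract_eigenvariate(V).series
        b = extract_eigenvariate(V).series
        assert np.array_equal(a, b)
        # aligned with the first voxel when the mean cancels
        assert np.corrcoef(a, s)[0, 1] > 0

    def test_denoising_recovers_common_signal(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=300)
        V = s[None, :] + rng.normal(0, 0.5, size=(50, 300))
        e = extract_eigenvariate(V).series
        assert abs(np.corrcoef(e, s)[0, 1]) >= 0.95

    def test_unit_variance(self):
        rng = np.random.default_rng(3)
        e = extract_eigenvariate(rng.normal(size=(5, 80))).series
        assert e.std(ddof=1) == pytest.approx(1.0)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            extract_eigenvariate(np.zeros((4, 50)))


@pytest.fixture(scope="module")
def op():
    return DeconvolutionOperator(n_scans=160, tr=1.6)


class TestDeconvolution:
    def test_zero_series_gives_zero_neural(self, op):
        assert not op.solve(np.zeros(160), 1.0).any()

    def test_forward_round_trip_on_band_limited_signal(self, op):
        """convolve(deconvolve(y)) ~ y for smooth neural input, small lambda."""
        rng = np.random.default_rng(0)
        from scipy.ndimage import gaussian_filter1d

        x_true = gaussian_filter1d(rng.normal(size=op.n_micro), sigma=20)
        y = hemo.convolve_to_scans(x_true, 1.6)
        x = op.solve(y, 1e-4)
        y_back = hemo.convolve_to_scans(x, 1.6)
        assert np.corrcoef(y_back, y)[0, 1] >= 0.99

    def test_neural_estimate_correlates_with_truth(self, op):
        rng = np.random.default_rng(1)
        from scipy.ndimage import gaussian_filter1d

        x_true = gaussian_filter1d(rng.normal(size=op.n_micro), sigma=30)
        y = hemo.convolve_to_scans(x_true, 1.6)
        x = op.solve(y, 1e-3)
        assert np.corrcoef(x, x_true)[0, 1] >= 0.95

    def test_large_lambda_flattens_estimate(self, op):
        rng = np.random.default_rng(2)
        y = rng.normal(size=160)
        x_small = op.solve(y, 1.0)
        x_large = op.solve(y, 1e6)
        assert np.ptp(x_large) < 0.05 * np.ptp(x_small)

    def test_negative_lambda_rejected(self, op):
        with pytest.raises(ValueError):
            op.solve(np.ones(160), -1.0)

    def test_gcv_prefers_small_lambda_for_clean_data(self, op):
        from scipy.ndimage import gaussian_filter1d

        rng = np.random.default_rng(3)
        x_true = gaussian_filter1d(rng.normal(size=op.n_micro), sigma=20)
        y_clean = hemo.convolve_to_scans(x_true, 1.6)
        lam_clean = op.gcv(y_clean, lambdas=np.logspace(-3, 3, 7))
        lam_noisy = op.gcv(y_clean + rng.normal(0, 5, 160),
                           lambdas=np.logspace(-3, 3, 7))
        assert lam_clean < lam_noisy

    def test_deconvolve_wrapper_matches_operator(self, op):
        rng = np.random.default_rng(4)
        y = rng.normal(size=160)
        a = deconvolve(y, tr=1.6, lam=1.0, operator=op)
        b = op.solve(y - y.mean(), 1.0)
        assert np.allclose(a, b)


class TestPPIRegressors:
    def test_balanced_psych_cancels_exactly(self):
        """+1/-1 impulses at scan-aligned onsets cancel after convolution."""
        neural = np.zeros(160 * 16)
        regs = ppi_regressors(neural, np.array([16.0, 48.0]), np.array([32.0, 64.0]),
                              1.6, 160)
        assert regs["psych"].sum() == pytest.approx(0.0, abs=1e-9)

    def test_unit_neural_makes_interaction_equal_psych(self):
        neural = np.ones(160 * 16)
        regs = ppi_regressors(neural, np.array([10.0]), np.array([60.0]), 1.6, 160)
        assert np.allclose(regs["ppi"], regs["psych"])

    def test_no_stop_events_rejected(self):
        with pytest.raises(ValueError, match="no Stop events"):
            ppi_regressors(np.zeros(160 * 16), np.array([]), np.array([]), 1.6, 160)

    def test_events_outside_window_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ppi_regressors(np.zeros(160 * 16), np.array([500.0]), np.array([]), 1.6, 160)

    def test_regressor_correlations_moderate_on_task_designs(
        self, mini_sequence, mini_scans
    ):
        """Physio/psych/interaction stay separable (all pairwise |r| < 0.7)."""
        op = DeconvolutionOperator(mini_scans, 1.6)
        worst = 0.0
        for s in range(5):
            g = np.random.default_rng([13, s])
            sess = simulate_session(mini_sequence, SubjectParams(), g)
            regions = [RegionSpec("seed", amp_stop_success=1.0, amp_stop_failure=0.3,
                                  amp_go=0.2, noise_sd=0.3, neural_noise_sd=1.0)]
            ds = synthesize_bold(mini_sequence, sess, regions, tr=1.6,
                                 n_scans=mini_scans, seed=g)
            neural = deconvolve(ds.region("seed"), tr=1.6, lam=1.0, operator=op)
            df = sess.trials
            regs = ppi_regressors(
                neural,
                df.loc[df.outcome == "StopSuccess", "onset"].to_numpy(),
                df.loc[df.outcome == "StopFailure", "onset"].to_numpy(),
                1.6, mini_scans,
            )
            c = regs.corr().abs().to_numpy()
            worst = max(worst, np.max(c[np.triu_indices(3, k=1)]))
        assert worst < 0.7


def _ppi_cohort_betas(sequence, n_scans, delta, n_subj, cohort_seed, op,
                      reverse=False):
    """Per-subject interaction betas for one simulated cohort."""
    betas = []
    for child in np.random.SeedSequence([cohort_seed, 17]).spawn(n_subj):
        g = np.random.default_rng(child)
        sess = simulate_session(sequence, SubjectParams(), g)
        regions = [
            RegionSpec("seed", amp_stop_success=1.0, amp_stop_failure=0.3,
                       amp_go=0.2, slope_pstop=0.5, noise_sd=0.3,
                       neural_noise_sd=1.0),
            RegionSpec("sink", amp_go=0.8, amp_stop_failure=0.6, slope_rt=0.3,
                       coupling_seed=0.2, coupling_delta=delta, noise_sd=1.0),
        ]
        ds = synthesize_bold(sequence, sess, regions, tr=1.6, n_scans=n_scans,
                             seed=g, seed_region="seed")
        seed_name, sink_name = ("sink", "seed") if reverse else ("seed", "sink")
        neural = deconvolve(ds.region(seed_name), tr=1.6, lam=1.0, operator=op)
        df = sess.trials
        regs = ppi_regressors(
            neural,
            df.loc[df.outcome == "StopSuccess", "onset"].to_numpy(),
            df.loc[df.outcome == "StopFailure", "onset"].to_numpy(),
            1.6, n_scans,
        )
        nuis = task_nuisance_regressors(sess, 1.6, n_scans)
        betas.append(
            PPIModel(ds.region(sink_name), regs, nuisance=nuis).fit().beta["ppi"]
        )
    return np.array(betas)


class TestPPIRecovery:
    def test_planted_negative_coupling_recovered(self, mini_sequence, mini_scans):
        op = DeconvolutionOperator(mini_scans, 1.6)
        betas = _ppi_cohort_betas(mini_sequence, mini_scans, -0.8, 12, 0, op)
        t, p = group_t(betas)
        assert t < 0 and p < 0.05

    def test_planted_positive_coupling_recovered(self, mini_sequence, mini_scans):
        op = DeconvolutionOperator(mini_scans, 1.6)
        betas = _ppi_cohort_betas(mini_sequence, mini_scans, +0.8, 12, 1, op)
        t, p = group_t(betas)
        assert t > 0 and p < 0.05

    def test_forward_ppi_outpowers_reverse(self, mini_sequence, mini_scans):
        """The planted coupling is seed->sink; the forward analysis shows a
        stronger group effect than the reverse (seed and sink exchanged)."""
        op = DeconvolutionOperator(mini_scans, 1.6)
        fwd = [abs(group_t(_ppi_cohort_betas(mini_sequence, mini_scans, -0.8,
                                             12, c, op))[0]) for c in range(3)]
        rev = [abs(group_t(_ppi_cohort_betas(mini_sequence, mini_scans, -0.8,
                                             12, c, op, reverse=True))[0])
               for c in range(3)]
        assert np.mean(fwd) > np.mean(rev)

    def test_estimate_invariant_to_seed_scaling(self, mini_sequence, mini_scans):
        """Rescaling the seed series rescales the beta but leaves t unchanged."""
        op = DeconvolutionOperator(mini_scans, 1.6)
        g = np.random.default_rng(5)
        sess = simulate_session(mini_sequence, SubjectParams(), g)
        regions = [
            RegionSpec("seed", amp_stop_success=1.0, noise_sd=0.3, neural_noise_sd=1.0),
            RegionSpec("sink", coupling_seed=0.2, coupling_delta=-0.8, noise_sd=1.0),
        ]
        ds = synthesize_bold(mini_sequence, sess, regions, tr=1.6,
                             n_scans=mini_scans, seed=g, seed_region="seed")
        df = sess.trials
        ss = df.loc[df.outcome == "StopSuccess", "onset"].to_numpy()
        sf = df.loc[df.outcome == "StopFailure", "onset"].to_numpy()
        results = []
        for scale in (1.0, 10.0):
            neural = deconvolve(scale * ds.region("seed"), tr=1.6, lam=1.0, operator=op)
            regs = ppi_regressors(neural, ss, sf, 1.6, mini_scans)
            results.append(PPIModel(ds.region("sink"), regs).fit())
        assert results[0].t["ppi"] == pytest.approx(results[1].t["ppi"], rel=1e-6)
        assert results[1].beta["ppi"] == pytest.approx(
            results[0].beta["ppi"] / 10.0, rel=1e-6
        )


class TestPPIModel:
    def test_collinear_regressors_rejected(self):
        n = 160
        rng = np.random.default_rng(0)
        base = rng.normal(size=n)
        regs = pd.DataFrame({"physio": base, "psych": base * 2.0, "ppi": rng.normal(size=n)})
        with pytest.raises(ValueError, match="collinear"):
            PPIModel(rng.normal(size=n), regs)

    def test_length_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        regs = pd.DataFrame({"physio": rng.normal(size=50),
                             "psych": rng.normal(size=50),
                             "ppi": rng.normal(size=50)})
        with pytest.raises(ValueError, match="scan count"):
            PPIModel(np.zeros(49), regs)

    def test_sign_attribute_consistent(self):
        rng = np.random.default_rng(1)
        n = 300
        regs = pd.DataFrame({"physio": rng.normal(size=n),
                             "psych": rng.normal(size=n),
                             "ppi": rng.normal(size=n)})
        sink = 2.0 * regs["ppi"].to_numpy() + rng.normal(size=n)
        res = PPIModel(sink, regs).fit()
        assert res.sign == "positive"
        assert "interaction" in res.summary()


def test_eigenvariate_of_tiled_phantom(mini_sequence, mini_session, mini_scans):
    """Sphere-like voxel tiling: the eigenvariate tracks the region signal."""
    regions = [RegionSpec("r", amp_stop_success=1.0, noise_sd=0.0)]
    ds = synthesize_bold(mini_sequence, mini_session, regions, tr=1.6,
                         n_scans=mini_scans, seed=0)
    vox = tile_region(ds, "r", n_voxels=60, noise_sd=1.0, seed=2)
    e = extract_eigenvariate(vox).series
    base = ds.region("r")
    assert np.corrcoef(e, base)[0, 1] > 0.9
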