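"""First-level GLM, contrasts, second-level tests and the RM-ANOVA."""

import numpy as np
import pandas as pd
import pytest

from stopsig.bold import RegionSpec, synthesize_bold
from stopsig.glm import (
    FirstLevelGLM,
    build_design_matrix,
    group_t,
    rm_anova_2way,
    rt_bin_cell_means,
)
from stopsig.race import SessionData, SubjectParams, simulate_session
from stopsig.task import TaskConfig, build_trial_sequence


class TestDesignMatrix:
    def test_column_layout(self, mini_sequence, mini_session, mini_scans):
        d = build_design_matrix(mini_sequence, mini_session, 1.6, mini_scans)
        for name in ("stop_success", "stop_failure", "go_exp", "rt_mod",
                     "pstop_mod", "rest", "constant"):
            assert name in d.names
        assert d.frame.shape[0] == mini_scans

    def test_modulators_centered_over_parent_events(self, mini_session):
        from stopsig.bold import standardized_modulators

        mods = standardized_modulators(mini_session)
        assert mods["rt"].mean() == pytest.approx(0.0, abs=1e-12)
        assert mods["pstop"].mean() == pytest.approx(0.0, abs=1e-12)
        assert mods["rt"].std(ddof=0) == pytest.approx(1.0, rel=1e-6)

    def test_modulator_correlation_low_on_canonical_design(
        self, paper_sequence, paper_session
    ):
        d = build_design_matrix(paper_sequence, paper_session, 1.6, 622)
        assert d.modulator_correlation < 0.4

    def test_constant_rts_break_rank(self, mini_sequence, mini_session, mini_scans):
        sess = SessionData(
            sequence=mini_session.sequence,
            trials=mini_session.trials.copy(),
            subject=mini_session.subject,
            seed=0,
        )
        go = (sess.trials.trial_type == "go") & (sess.trials.level > 0)
        sess.trials.loc[go, "rt"] = 820.0
        with pytest.raises(ValueError, match="rank|collinear"):
            build_design_matrix(mini_sequence, sess, 1.6, mini_scans)

    def test_no_events_leaves_drift_only(self):
        cfg = TaskConfig(
            levels=(("green", 0.0),), n_stop_per_level=(0,), n_go_baseline=24,
            block_size_range=(12, 15), rest_blocks=(),
        )
        seq = build_trial_sequence(cfg, seed=0, screen_regressors=False)
        sess = simulate_session(seq, SubjectParams(), seed=0)
        d = build_design_matrix(seq, sess, 1.6, 100)
        assert all(c.startswith("dct_") or c == "constant" for c in d.names)

    def test_rest_block_regressor_present(self, paper_sequence, paper_session):
        d = build_design_matrix(paper_sequence, paper_session, 1.6, 622)
        assert "rest" in d.names
        assert d.frame["rest"].max() > 0


class TestFit:
    def test_noiseless_betas_exact(self, mini_sequence, mini_session, mini_scans):
        d = build_design_matrix(mini_sequence, mini_session, 1.6, mini_scans)
        rng = np.random.default_rng(0)
        beta_true = rng.normal(size=d.frame.shape[1])
        y = d.matrix @ beta_true
        res = FirstLevelGLM(y[None, :], d).fit(prewhiten=False)
        assert np.allclose(res.params.iloc[:, 0], beta_true, atol=1e-8)

    def test_rho_recovered_from_ar1_noise(self, mini_sequence, mini_session):
        regions = [RegionSpec("n", noise_sd=1.0, ar1_rho=0.3)]
        d = build_design_matrix(mini_sequence, mini_session, 1.6, 616)
        rhos = []
        for s in range(6):
            ds = synthesize_bold(mini_sequence, mini_session, regions, tr=1.6,
                                 n_scans=616, seed=s)
            rhos.append(FirstLevelGLM(ds.signal, d).fit().rho)
        assert abs(np.mean(rhos) - 0.3) < 0.1

    def test_whitening_reduces_residual_autocorrelation(
        self, mini_sequence, mini_session
    ):
        from stopsig.glm import _lag1_autocorr

        regions = [RegionSpec("n", noise_sd=1.0, ar1_rho=0.4)]
        d = build_design_matrix(mini_sequence, mini_session, 1.6, 616)
        better = 0
        for s in range(10):
            ds = synthesize_bold(mini_sequence, mini_session, regions, tr=1.6,
                                 n_scans=616, seed=s)
            m = FirstLevelGLM(ds.signal, d)
            r_before = float(np.mean(_lag1_autocorr(
                m.Y - d.matrix @ np.linalg.lstsq(d.matrix, m.Y, rcond=None)[0]
            )))
            r_after = float(np.mean(_lag1_autocorr(m.fit().residuals)))
            better += abs(r_after) < abs(r_before)
        assert better >= 9

    def test_too_many_regressors_rejected(self, mini_sequence, mini_session, mini_scans):
        d = build_design_matrix(mini_sequence, mini_session, 1.6, mini_scans)
        with pytest.raises(ValueError):
            FirstLevelGLM(np.zeros((1, d.frame.shape[1] - 1)), d)


@pytest.fixture(scope="module")
def fitted(mini_sequence, mini_session, mini_scans):
    regions = [RegionSpec("a", amp_stop_success=1.3, amp_stop_failure=0.3,
                          noise_sd=0.0)]
    ds = synthesize_bold(mini_sequence, mini_session, regions, tr=1.6,
                         n_scans=mini_scans, seed=0)
    d = build_design_matrix(mini_sequence, mini_session, 1.6, mini_scans)
    return FirstLevelGLM(ds.signal, d).fit(prewhiten=False)


class TestContrast:
    def test_planted_difference_recovered(self, fitted):
        con = fitted.contrast("stop_success_gt_failure")
        assert con.estimate.iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_sign_flip_negates_estimate(self, fitted):
        a = fitted.contrast({"stop_success": 1.0, "stop_failure": -1.0})
        b = fitted.contrast({"stop_success": -1.0, "stop_failure": 1.0})
        assert a.estimate.iloc[0] == pytest.approx(-b.estimate.iloc[0])

    def test_zero_weights_rejected(self, fitted):
        with pytest.raises(ValueError, match="zero"):
            fitted.contrast({"stop_success": 0.0})

    def test_unknown_regressor_rejected(self, fitted):
        with pytest.raises(ValueError, match="unknown"):
            fitted.contrast({"not_a_column": 1.0})

    def test_detection_power_on_noisy_region(self, paper_sequence, paper_session):
        """StopSuccess>StopFailure (planted 1 vs 0.3, noise 1): positive t in
        nearly every replicate of the full-scale design."""
        regions = [RegionSpec("a", amp_stop_success=1.0, amp_stop_failure=0.3,
                              noise_sd=1.0)]
        d = build_design_matrix(paper_sequence, paper_session, 1.6, 622)
        pos = 0
        for s in range(30):
            ds = synthesize_bold(paper_sequence, paper_session, regions, tr=1.6,
                                 n_scans=622, seed=s)
            t = FirstLevelGLM(ds.signal, d).fit().contrast(
                "stop_success_gt_failure"
            ).t.iloc[0]
            pos += t > 0
        assert pos >= 29

    def test_summary_renders(self, fitted):
        s = fitted.summary()
        assert "rho" in s and "stop_success" in s


class TestGroupT:
    def test_hand_computed_case(self):
        t, p = group_t([2, 0, 4, 2])
        assert t == pytest.approx(2.449, abs=1e-3)

    def test_symmetric_values_give_zero(self):
        t, _ = group_t([-1.5, 1.5])
        assert t == 0.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            group_t([1.0, 1.0, 1.0])

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            group_t([1.0])


class TestRMAnova:
    def test_constant_cells_give_zero_f(self):
        tab = rm_anova_2way(np.full((6, 4, 2), 3.3))
        assert (tab["F"] == 0.0).all()
        assert (tab["p"] == 1.0).all()

    def test_epsilon_within_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            tab = rm_anova_2way(rng.normal(size=(12, 4, 2)))
            eps = tab.loc["p_stop", "epsilon"]
            assert 1.0 / 3.0 <= eps <= 1.0
            assert tab.loc["rt_bin", "epsilon"] == 1.0

    def test_planted_main_effect_detected(self):
        """Cell means rising 0.5 per probability level: strong main effect,
        no RT-bin effect."""
        rng = np.random.default_rng(2)
        hits_p = hits_rt = 0
        n_rep = 30
        for _ in range(n_rep):
            v = rng.normal(size=(24, 4, 2)) + 0.5 * np.arange(4)[None, :, None]
            tab = rm_anova_2way(v)
            hits_p += tab.loc["p_stop", "p"] < 0.05
            hits_rt += tab.loc["rt_bin", "p"] < 0.05
        assert hits_p >= int(0.8 * n_rep)
        assert hits_rt <= int(0.2 * n_rep)

    def test_missing_cells_rejected(self):
        v = np.ones((5, 4, 2))
        v[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova_2way(v)

    def test_f_matches_statsmodels_uncorrected(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(5)
        v = rng.normal(size=(10, 4, 2))
        tab = rm_anova_2way(v)
        n, a, b = v.shape
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(n), a * b),
            "p_stop": np.tile(np.repeat(np.arange(a), b), n),
            "rt_bin": np.tile(np.arange(b), n * a),
            "value": v.reshape(-1),
        })
        ref = AnovaRM(long, "value", "subject", within=["p_stop", "rt_bin"]).fit()
        assert tab.loc["p_stop", "F"] == pytest.approx(
            ref.anova_table.loc["p_stop", "F Value"]
        )

    def test_epsilon_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        v = rng.normal(size=(15, 4, 2))
        tab = rm_anova_2way(v)
        marg = pd.DataFrame(v.mean(axis=2))
        eps_ref = pingouin.epsilon(marg, correction="gg")
        assert tab.loc["p_stop", "epsilon"] == pytest.approx(eps_ref, rel=1e-6)


def test_rt_bin_cell_means_median_split(paper_session):
    cells = rt_bin_cell_means(paper_session)
    assert cells.shape == (4, 2)
    assert (cells[:, 1] > cells[:, 0]).all()  # slow bin mean exceeds fast bin


class TestPermutationClusterTest:
    def test_planted_contiguous_effect_detected(self):
        from stopsig.glm import permutation_cluster_test

        rng = np.random.default_rng(4)
        X = rng.normal(size=(16, 60))
        X[:, 20:30] += 1.2  # contiguous planted effect
        tab = permutation_cluster_test(X, threshold=2.0, n_perm=500, seed=0)
        hits = tab[(tab.start >= 18) & (tab.end <= 32)]
        assert len(hits) >= 1
        assert hits["p"].min() < 0.05

    def test_null_data_yields_no_small_p(self):
        from stopsig.glm import permutation_cluster_test

        rng = np.random.default_rng(5)
        tab = permutation_cluster_test(rng.normal(size=(16, 60)),
                                       threshold=2.0, n_perm=500, seed=0)
        assert tab.empty or tab["p"].min() > 0.05

    def test_input_validation(self):
        from stopsig.glm import permutation_cluster_test

        with pytest.raises(ValueError):
            permutation_cluster_test(np.ones((1, 10)))
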