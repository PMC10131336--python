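import numpy as np
import pytest
from scipy import special

from toplinegs.io_kinship import KinshipMatrix, compute_grm
from toplinegs.models import (
    GBLUPFit,
    McmcConfig,
    ModelError,
    TGBLUPFit,
    fit_gblup,
    fit_tgblup,
    predict_gblup,
    predict_tgblup_proba,
)
from toplinegs.synthetic_data import SimConfig, simulate_genotypes, simulate_phenotypes

from conftest import random_marker_matrix


def blup_oracle(G, y_obs_mask, y, lam):
    """Independent dense closed-form solve: GLS intercept, then the
    generalized-ridge conditional mean g = G[:,obs] (G_oo + lam I)^-1 r."""
    obs = y_obs_mask
    G_oo = G[np.ix_(obs, obs)]
    n = int(obs.sum())
    V = G_oo + lam * np.eye(n)
    Vinv = np.linalg.inv(V)
    ones = np.ones(n)
    mu = (ones @ Vinv @ y[obs]) / (ones @ Vinv @ ones)
    g = G[:, obs] @ Vinv @ (y[obs] - mu)
    return mu, g


# fixed 6-line fixture: G from a tiny dosage matrix, y printed
FIX_DOSAGES = np.array([
    [0, 2, 1, 0, 2, 1, 0, 2],
    [0, 2, 1, 0, 2, 0, 1, 2],
    [2, 0, 1, 2, 0, 1, 2, 0],
    [2, 0, 0, 2, 1, 1, 2, 0],
    [1, 1, 2, 1, 1, 2, 0, 1],
    [0, 1, 1, 0, 2, 2, 1, 1],
], dtype=float)
FIX_Y = np.array([10.4, 9.8, 12.1, 11.7, 10.0, 9.2])


class TestGblupDeterministic:
    def test_no_signal_constant_y(self):
        n = 25
        K = KinshipMatrix([f"L{i}" for i in range(n)], np.eye(n))
        fit = fit_gblup(np.full(n, 3.7), K, mode="blup_deterministic")
        assert fit.mu == pytest.approx(3.7)
        np.testing.assert_allclose(fit.g_hat, 0.0, atol=1e-10)
        assert fit.sigma2_g == pytest.approx(0.0, abs=1e-10)

    def test_six_line_fixture_matches_oracle(self):
        ids = [f"L{i}" for i in range(6)]
        K = compute_grm(
            __import__("toplinegs.io_kinship", fromlist=["MarkerMatrix"])
            .MarkerMatrix(ids, [f"M{j}" for j in range(8)], FIX_DOSAGES)
        )
        lam = 1.5
        fit = fit_gblup(FIX_Y, K, mode="blup_deterministic",
                        lambda_fixed=lam, min_observed=1)
        mu, g = blup_oracle(K.G, np.ones(6, dtype=bool), FIX_Y, lam)
        assert fit.mu == pytest.approx(mu, abs=1e-8)
        np.testing.assert_allclose(fit.g_hat, g, atol=1e-8)

    def test_random_instances_match_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(8, 31))
            M = random_marker_matrix(rng, n, 60)
            K = compute_grm(M)
            y = rng.normal(size=n)
            mask = np.ones(n, dtype=bool)
            n_test = int(rng.integers(0, n // 3 + 1))
            if n_test:
                mask[rng.choice(n, n_test, replace=False)] = False
            yv = np.where(mask, y, np.nan)
            lam = float(rng.uniform(0.1, 5.0))
            fit = fit_gblup(yv, K, mode="blup_deterministic",
                            lambda_fixed=lam, min_observed=1)
            mu, g = blup_oracle(K.G, mask, y, lam)
            assert fit.mu == pytest.approx(mu, abs=1e-8)
            np.testing.assert_allclose(fit.g_hat, g, atol=1e-8)

    def test_identical_g_rows_predict_equal(self):
        # two test lines with identical genotypes get identical predictions
        dos = np.vstack([FIX_DOSAGES, FIX_DOSAGES[0], FIX_DOSAGES[0]])
        ids = [f"L{i}" for i in range(8)]
        from toplinegs.io_kinship import MarkerMatrix
        K = compute_grm(MarkerMatrix(ids, [f"M{j}" for j in range(8)], dos))
        y = np.concatenate([FIX_Y, [np.nan, np.nan]])
        fit = fit_gblup(y, K, mode="blup_deterministic", min_observed=1)
        preds = predict_gblup(fit, ["L6", "L7"])
        assert preds[0] == pytest.approx(preds[1], abs=1e-10)

    def test_reml_recovers_h2(self, sim_kinship):
        K, pheno, truth = sim_kinship
        fit = fit_gblup(pheno.values, K, mode="blup_deterministic")
        assert fit.heritability == pytest.approx(truth.realized_h2, abs=0.25)

    def test_prediction_correlates_with_truth(self, sim_kinship):
        K, pheno, truth = sim_kinship
        y = pheno.values.copy()
        te = np.arange(40)
        y[te] = np.nan
        fit = fit_gblup(y, K, mode="blup_deterministic")
        preds = predict_gblup(fit, [K.line_ids[i] for i in te])
        r = np.corrcoef(preds, truth.g_true[te])[0, 1]
        assert r > 0.2

    def test_too_few_observed(self):
        K = KinshipMatrix([f"L{i}" for i in range(30)], np.eye(30))
        y = np.full(30, np.nan)
        y[:10] = 1.0
        with pytest.raises(ModelError, match="observed"):
            fit_gblup(y, K, mode="blup_deterministic")

    def test_non_psd_rejected(self):
        n = 10
        G = -np.eye(n)
        K = KinshipMatrix.__new__(KinshipMatrix)
        K.line_ids = [f"L{i}" for i in range(n)]
        K.G = G
        with pytest.raises(ModelError, match="PSD"):
            fit_gblup(np.ones(n) + np.arange(n), K,
                      mode="blup_deterministic", min_observed=1)

    def test_unknown_id_error(self, sim_kinship):
        K, pheno, _ = sim_kinship
        fit = fit_gblup(pheno.values, K, mode="blup_deterministic")
        with pytest.raises(ModelError, match="unknown"):
            predict_gblup(fit, ["NOPE"])


class TestGblupGibbs:
    def test_fixed_variance_converges_to_blup(self, rng):
        M = random_marker_matrix(rng, 100, 300)
        K = compute_grm(M)
        y = rng.normal(10, 2, size=100)
        y[:20] = np.nan
        s2g = s2e = 2.0
        det = fit_gblup(y, K, mode="blup_deterministic", lambda_fixed=s2e / s2g)
        gib = fit_gblup(
            y, K, cfg=McmcConfig(n_iter=12000, burn_in=2000, thin=2, seed=9),
            mode="gibbs", fixed_variances=(s2g, s2e),
        )
        S = gib.mcmc_meta["n_retained"]
        mcse = gib.g_sd / np.sqrt(S / 10)  # conservative effective sample size
        assert np.all(np.abs(gib.g_hat - det.g_hat) < 3 * mcse)

    def test_seed_reproducibility_bitwise(self, sim_kinship):
        K, pheno, _ = sim_kinship
        cfg = McmcConfig(n_iter=600, burn_in=100, thin=2, seed=4)
        y = pheno.values.copy()
        y[:30] = np.nan
        a = fit_gblup(y, K, cfg=cfg, mode="gibbs")
        b = fit_gblup(y, K, cfg=cfg, mode="gibbs")
        assert a.mu == b.mu and a.sigma2_g == b.sigma2_g
        np.testing.assert_array_equal(a.g_hat, b.g_hat)

    def test_gibbs_recovers_h2_single(self):
        cfg = SimConfig(n_lines=400, n_markers=800, n_qtl=200, h2=0.5,
                        seed=11, inbreeding=0.0)
        M = simulate_genotypes(cfg)
        pheno, truth = simulate_phenotypes(M, cfg)
        K = compute_grm(M)
        fit = fit_gblup(pheno.values, K,
                        cfg=McmcConfig(n_iter=6000, burn_in=1000, seed=1),
                        mode="gibbs")
        assert abs(fit.heritability - 0.5) < 0.12

    def test_serialization(self, tmp_path, sim_kinship):
        K, pheno, _ = sim_kinship
        fit = fit_gblup(pheno.values, K, mode="blup_deterministic")
        path = tmp_path / "fit.json"
        fit.to_json(path)
        import json
        d = json.loads(path.read_text())
        assert d["model"] == "gblup"
        assert len(d["lines"]) == len(K.line_ids)


class TestTgblup:
    def make_labels(self, K, beta0, rng, scale=1.0):
        L = np.linalg.cholesky(K.G + 1e-8 * np.eye(len(K.line_ids)))
        g = scale * (L @ rng.standard_normal(len(K.line_ids)))
        return (rng.uniform(size=len(K.line_ids))
                < special.ndtr(beta0 + g)).astype(float), g

    def test_single_class_error(self):
        K = KinshipMatrix([f"L{i}" for i in range(30)], np.eye(30))
        with pytest.raises(ModelError, match="one class"):
            fit_tgblup(np.ones(30), K)

    def test_beta0_recovery(self, rng):
        M = random_marker_matrix(rng, 400, 600, inbred=True)
        K = compute_grm(M)
        yb, _ = self.make_labels(K, -0.8, rng)
        fit = fit_tgblup(yb, K, cfg=McmcConfig(n_iter=6000, burn_in=1000,
                                               thin=5, seed=2))
        assert abs(fit.beta0 - (-0.8)) < 0.35

    def test_null_probs_near_prevalence(self):
        K = KinshipMatrix([f"L{i}" for i in range(200)], np.eye(200))
        yb = np.array([0.0, 1.0] * 100)
        fit = fit_tgblup(yb, K, cfg=McmcConfig(n_iter=3000, burn_in=1000,
                                               seed=0))
        p = predict_tgblup_proba(fit, K.line_ids)
        assert abs(p.mean() - 0.5) < 0.05
        assert np.mean(np.abs(p - 0.5) < 0.3) > 0.9

    def test_probs_in_unit_interval(self, rng):
        M = random_marker_matrix(rng, 150, 200)
        K = compute_grm(M)
        yb, _ = self.make_labels(K, -0.5, rng)
        yb[100:] = np.nan
        fit = fit_tgblup(yb, K, cfg=McmcConfig(n_iter=1000, burn_in=200,
                                               seed=3))
        p = predict_tgblup_proba(fit, K.line_ids)
        assert np.all((p >= 0) & (p <= 1))

    def test_phi_zero_gives_half(self):
        # constructed fit with eta identically 0 across retained samples
        fit = TGBLUPFit(
            beta0=0.0, g_hat=np.zeros(3), sigma2_g=0.1,
            train_ids=["a"], all_ids=["a", "b", "c"],
            proba_mean_phi=special.ndtr(np.zeros(3)),
            proba_phi_mean=special.ndtr(np.zeros(3)),
        )
        np.testing.assert_allclose(predict_tgblup_proba(fit, ["b"]), 0.5)

    def test_monotone_in_g(self):
        # averaging Phi preserves samplewise ordering of the linear predictor
        rng = np.random.default_rng(5)
        b = rng.normal(size=50)
        gi = rng.normal(size=50)
        gj = gi - np.abs(rng.normal(size=50))  # gj <= gi samplewise
        pi = special.ndtr(b + gi).mean()
        pj = special.ndtr(b + gj).mean()
        assert pi >= pj

    def test_permutation_equivariance(self, rng):
        M = random_marker_matrix(rng, 80, 150)
        K = compute_grm(M)
        yb, _ = self.make_labels(K, -0.3, rng)
        cfg = McmcConfig(n_iter=800, burn_in=200, seed=6)
        fit = fit_tgblup(yb, K, cfg=cfg)
        perm = rng.permutation(80)
        K2 = KinshipMatrix([K.line_ids[i] for i in perm],
                           K.G[np.ix_(perm, perm)])
        fit2 = fit_tgblup(yb[perm], K2, cfg=cfg)
        p1 = predict_tgblup_proba(fit, K.line_ids)
        p2 = predict_tgblup_proba(fit2, K.line_ids)
        # same posterior law; finite-sample MCMC difference only
        assert np.corrcoef(p1, p2)[0, 1] > 0.95

    def test_bad_labels_rejected(self):
        K = KinshipMatrix([f"L{i}" for i in range(5)], np.eye(5))
        with pytest.raises(ModelError, match="0/1"):
            fit_tgblup(np.array([0.0, 1.0, 2.0, 0.0, 1.0]), K)

    def test_proba_mode_switch(self, rng):
        M = random_marker_matrix(rng, 60, 100)
        K = compute_grm(M)
        yb, _ = self.make_labels(K, 0.0, rng)
        fit = fit_tgblup(yb, K, cfg=McmcConfig(n_iter=500, burn_in=100, seed=7))
        a = predict_tgblup_proba(fit, K.line_ids, "posterior_mean_of_phi")
        b = predict_tgblup_proba(fit, K.line_ids, "phi_of_posterior_mean")
        assert a.shape == b.shape
        with pytest.raises(ModelError):
            predict_tgblup_proba(fit, K.line_ids, "nope")


class TestMcmcConfig:
    def test_burnin_validation(self):
        with pytest.raises(ModelError):
            McmcConfig(n_iter=100, burn_in=100)

    def test_thin_validation(self):
        with pytest.raises(ModelError):
            McmcConfig(thin=0)

    def test_n_retained(self):
        assert McmcConfig(n_iter=6000, burn_in=1000, thin=5).n_retained == 1000
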