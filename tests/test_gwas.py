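"""Mixed-model machinery: kinship and PCA oracles, rotated-likelihood
equivalence with the dense multivariate normal, GLS/OLS reductions of the
association tests, and variance-component estimation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import milletpop as mp
from milletpop.core import MISSING
from milletpop.gwas import MixedLMM, he_regression
from milletpop.simulate import TraitArchitecture, simulate_phenotypes, simulate_related_panel

from conftest import make_matrix


@pytest.fixture(scope="module")
def panel():
    return simulate_related_panel(120, 300, seed=1)


@pytest.fixture(scope="module")
def panel_K(panel):
    K, m = mp.kinship(panel)
    return K


class TestKinship:
    def test_identical_individuals_share_rows(self):
        G = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 0]], dtype=np.int8)
        g = make_matrix(G)
        K, m = mp.kinship(g)
        assert np.allclose(K[0], K[1])
        assert np.allclose(K[:, 0], K[:, 1])

    def test_monomorphic_sites_skipped_in_standardized_method(self):
        G = np.array([[0, 1], [0, 2], [0, 0]], dtype=np.int8)
        g = make_matrix(G)
        K, m = mp.kinship(g, "standardized")
        assert m == 1
        with pytest.raises(ValueError):
            mp.kinship(make_matrix(np.zeros((3, 2), dtype=np.int8)))

    def test_matches_direct_summation_formula(self):
        rng = np.random.default_rng(3)
        G = rng.integers(0, 3, size=(5, 8)).astype(np.int8)
        g = make_matrix(G)
        K, m = mp.kinship(g, "standardized")
        X = G.astype(float)
        f = X.mean(axis=0) / 2
        poly = (f > 0) & (f < 1)
        acc = np.zeros((5, 5))
        used = 0
        for j in range(8):
            if not poly[j]:
                continue
            z = (X[:, j] - 2 * f[j]) / np.sqrt(2 * f[j] * (1 - f[j]))
            acc += np.outer(z, z)
            used += 1
        assert m == used
        assert np.allclose(K, acc / used)

    def test_missing_genotypes_mean_imputed(self):
        G = np.array([[0, MISSING], [1, 2], [2, 0]], dtype=np.int8)
        g = make_matrix(G)
        K, m = mp.kinship(g)  # must not raise; imputation fills the gap
        assert np.isfinite(K).all()


class TestPca:
    def test_separates_two_populations(self):
        rng = np.random.default_rng(5)
        f1 = rng.uniform(0.05, 0.3, 200)
        f2 = rng.uniform(0.7, 0.95, 200)
        G = np.vstack([rng.binomial(2, f1, (30, 200)),
                       rng.binomial(2, f2, (30, 200))]).astype(np.int8)
        g = make_matrix(G)
        scores, explained = mp.pca(g, 2)
        labels = np.r_[np.zeros(30), np.ones(30)]
        r = np.corrcoef(scores[:, 0], labels)[0, 1]
        assert abs(r) > 0.9

    def test_explained_fractions_non_increasing_and_bounded(self, panel):
        scores, explained = mp.pca(panel, 5)
        assert explained.sum() <= 1.0 + 1e-12
        assert (np.diff(explained) <= 1e-12).all()

    def test_agrees_with_kinship_eigenvectors(self, panel):
        # centered-kinship eigenvectors and genotype SVD agree up to sign
        scores, _ = mp.pca(panel, 3)
        K, _ = mp.kinship(panel, "centered")
        w, U = np.linalg.eigh(K)
        for j in range(3):
            v = U[:, -1 - j]
            c = abs(np.corrcoef(scores[:, j], v)[0, 1])
            assert c > 1 - 1e-8

    def test_k_must_be_smaller_than_n(self, panel):
        with pytest.raises(ValueError):
            mp.pca(panel, panel.n_samples)


class TestMixedLMM:
    def test_rotated_likelihood_equals_dense_mvn(self, panel, panel_K):
        # ML log-likelihood via the eigen-rotation equals the dense
        # multivariate-normal evaluation on a 25-sample toy
        n = 25
        rng = np.random.default_rng(7)
        K = panel_K[:n, :n]
        y = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        mdl = MixedLMM(y, K, X)
        for lam in (0.1, 1.0, 10.0):
            beta, _, rss, _ = mdl._gls(lam)
            se2 = rss / n
            V = se2 * (lam * K + np.eye(n))
            dense = stats.multivariate_normal.logpdf(y, mean=X @ beta, cov=V)
            assert mdl.loglike_ml(lam) == pytest.approx(dense, rel=1e-8)

    def test_gls_matches_dense_inversion_at_fixed_lambda(self, panel, panel_K):
        n = 20
        rng = np.random.default_rng(11)
        K = panel_K[:n, :n]
        y = rng.standard_normal(n)
        x = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x])
        mdl = MixedLMM(y, K, X)
        lam = 2.5
        V = lam * K + np.eye(n)
        Vi = np.linalg.inv(V)
        beta_dense = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        beta, XtDX_inv, rss, _ = mdl._gls(lam)
        assert np.allclose(beta, beta_dense, rtol=1e-9)
        se_dense = np.sqrt(np.diag(np.linalg.inv(X.T @ Vi @ X)) * rss / (n - 2))
        se = np.sqrt(np.diag(XtDX_inv) * rss / (n - 2))
        assert np.allclose(se, se_dense, rtol=1e-9)

    def test_identity_kinship_reduces_to_ols(self):
        rng = np.random.default_rng(13)
        n = 60
        y = rng.standard_normal(n)
        G = rng.integers(0, 3, size=(n, 6)).astype(np.int8)
        g = make_matrix(G)
        assoc = mp.lmm_assoc(y, g, np.eye(n))
        for j in range(6):
            x = G[:, j].astype(float)
            X = np.column_stack([np.ones(n), x])
            bhat = np.linalg.lstsq(X, y, rcond=None)[0]
            resid = y - X @ bhat
            s2 = resid @ resid / (n - 2)
            se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
            t = bhat[1] / se
            p_ols = 2 * stats.t.sf(abs(t), n - 2)
            assert assoc["p_wald"][j] == pytest.approx(p_ols, rel=1e-6)

    def test_collinear_covariates_rejected_with_column_named(self, panel_K):
        n = panel_K.shape[0]
        X = np.column_stack([np.ones(n), np.ones(n)])
        with pytest.raises(ValueError, match="collinear"):
            MixedLMM(np.zeros(n) + np.arange(n), panel_K, X)

    def test_non_psd_kinship_rejected(self):
        n = 10
        K = -np.eye(n)
        with pytest.raises(ValueError, match="positive semidefinite"):
            MixedLMM(np.arange(n, dtype=float), K)

    def test_pvalues_invariant_to_consistent_sample_reordering(self, panel, panel_K):
        rng = np.random.default_rng(17)
        n = panel.n_samples
        y = rng.standard_normal(n)
        sub = panel.take_variants(np.arange(10))
        a1 = mp.lmm_assoc(y, sub, panel_K)
        perm = rng.permutation(n)
        sub2 = sub.take_samples([sub.samples[i] for i in perm])
        a2 = mp.lmm_assoc(y[perm], sub2, panel_K[np.ix_(perm, perm)])
        assert np.allclose(a1["p_wald"], a2["p_wald"], rtol=1e-6)

    def test_three_tests_agree_asymptotically(self):
        # at n = 1000 samples the -log10 p of Wald, LRT, score correlate
        n = 1000
        g = simulate_related_panel(n, 400, n_founders=100, seed=21)
        rng = np.random.default_rng(23)
        K, _ = mp.kinship(g)
        beta = np.zeros(400)
        # moderate effects: the three tests coincide asymptotically but
        # diverge for extreme signals, so keep top hits around p ~ 1e-5
        beta[rng.choice(400, 20, replace=False)] = 0.04 * rng.standard_normal(20)
        X = g.G.astype(float)
        gv = (X - X.mean(axis=0)) @ beta
        y = gv + rng.standard_normal(n) * max(gv.std(), 0.5)
        assoc = mp.lmm_assoc(y, g, K).dropna()
        lw = -np.log10(assoc["p_wald"])
        assert np.corrcoef(lw, -np.log10(assoc["p_lrt"]))[0, 1] > 0.99
        assert np.corrcoef(lw, -np.log10(assoc["p_score"]))[0, 1] > 0.99


class TestThresholds:
    @pytest.mark.parametrize("n,expected", [
        (5_000_000, 1e-8), (50, 1e-3), (1, 0.05),
    ])
    def test_bonferroni(self, n, expected):
        thr = mp.significance_thresholds(n)
        assert thr["bonferroni"] == pytest.approx(expected)
        assert thr["genomewide"] == 1e-8


class TestHeritability:
    def test_pure_genetic_value_gives_h2_near_one(self):
        g = simulate_related_panel(200, 500, seed=31)
        phen, truth = simulate_phenotypes(
            g, TraitArchitecture(n_causal=100, h2=(1.0,), seed=32))
        K, _ = mp.kinship(g)
        res = mp.reml_h2(phen.iloc[:, 0].to_numpy(), K)
        assert res.h2 > 0.95

    def test_pure_noise_gives_h2_near_zero(self):
        g = simulate_related_panel(200, 500, seed=33)
        rng = np.random.default_rng(34)
        K, _ = mp.kinship(g)
        res = mp.reml_h2(rng.standard_normal(200), K)
        assert res.h2 < 0.15

    def test_h2_invariant_to_phenotype_scaling(self):
        g = simulate_related_panel(150, 400, seed=35)
        phen, _ = simulate_phenotypes(
            g, TraitArchitecture(n_causal=100, h2=(0.5,), seed=36))
        K, _ = mp.kinship(g)
        y = phen.iloc[:, 0].to_numpy()
        r1 = mp.reml_h2(y, K)
        r2 = mp.reml_h2(1000.0 * y, K)
        assert r1.h2 == pytest.approx(r2.h2, abs=1e-6)

    def test_summary_mentions_the_estimates(self):
        g = simulate_related_panel(100, 300, seed=37)
        phen, _ = simulate_phenotypes(
            g, TraitArchitecture(n_causal=50, h2=(0.5,), seed=38))
        K, _ = mp.kinship(g)
        text = mp.reml_h2(phen.iloc[:, 0].to_numpy(), K).summary()
        assert "h2" in text and "sigma_g^2" in text


class TestGeneticCorrelation:
    def test_identical_traits_give_rg_one(self):
        g = simulate_related_panel(150, 400, seed=41)
        phen, _ = simulate_phenotypes(
            g, TraitArchitecture(n_causal=100, h2=(0.6,), seed=42))
        K, _ = mp.kinship(g)
        y = phen.iloc[:, 0].to_numpy()
        res = mp.reml_rg(y, y.copy(), K)
        # the boundary is approached through the log-Cholesky interior
        assert res.r_g == pytest.approx(1.0, abs=0.01)

    def test_he_regression_tracks_reml(self):
        g = simulate_related_panel(250, 600, seed=43)
        phen, _ = simulate_phenotypes(
            g, TraitArchitecture(n_causal=150, h2=(0.5, 0.5), r_g=0.5, seed=44))
        K, _ = mp.kinship(g)
        res = mp.reml_rg(phen.iloc[:, 0].to_numpy(), phen.iloc[:, 1].to_numpy(), K)
        assert np.isfinite(res.he_r_g)
        assert abs(res.r_g - res.he_r_g) < 0.4

    def test_too_few_joint_samples_rejected(self):
        K = np.eye(10)
        with pytest.raises(ValueError):
            mp.reml_rg(np.zeros(10), np.zeros(10), K)
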