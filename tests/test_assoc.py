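"""Association models: OLS/GLS oracles, REML recovery, calibration trends."""

import numpy as np
import pytest
from scipy import stats

import popassoc as pa
from popassoc.data_io import GenotypeMatrix


def _geno(dosages):
    dosages = np.asarray(dosages, dtype=np.int8)
    m, n = dosages.shape
    return GenotypeMatrix(
        dosages=dosages,
        locus_ids=[f"L{i}" for i in range(m)],
        individual_ids=[f"I{j}" for j in range(n)],
    )


@pytest.fixture(scope="module")
def toy30():
    """n=30, m=3 dataset with two covariates and a structured trait."""
    rng = np.random.default_rng(101)
    X = rng.integers(0, 3, size=(3, 30)).astype(np.int8)
    Z = rng.standard_normal((30, 2))
    y = 0.4 * X[0] + Z @ np.array([0.5, -0.2]) + rng.standard_normal(30)
    return _geno(X), y, Z


class TestComputePcs:
    def test_zero_pcs_empty(self, admix_geno_200):
        U = pa.compute_pcs(admix_geno_200[0], 0)
        assert U.shape == (200, 0)

    def test_orthonormal_and_orthogonal_to_ones(self, admix_geno_200):
        U = pa.compute_pcs(admix_geno_200[0], 5)
        np.testing.assert_allclose(U.T @ U, np.eye(5), atol=1e-10)
        assert np.abs(U.T @ np.ones(200)).max() < 1e-8

    def test_r_too_large(self, admix_geno_200):
        with pytest.raises(ValueError):
            pa.compute_pcs(admix_geno_200[0], 200)

    def test_accepts_precomputed_kinship(self, admix_geno_200):
        G, _ = admix_geno_200
        phi = pa.standard_kinship(G)
        U = pa.compute_pcs(phi, 3)
        assert U.shape == (200, 3)


class TestPcaAssoc:
    def test_matches_statsmodels_ols(self, toy30):
        """Independent oracle: per-locus OLS fit via statsmodels."""
        import statsmodels.api as sm

        G, y, Z = toy30
        U = np.linalg.qr(np.random.default_rng(0).standard_normal((30, 2)))[0]
        res = pa.pca_assoc(G, y, U=U, Z=Z)
        for i in range(G.m):
            design = np.column_stack(
                [np.ones(30), G.dosages[i].astype(float), U, Z]
            )
            fit = sm.OLS(y, design).fit()
            assert res.beta[i] == pytest.approx(fit.params[1], abs=1e-8)
            assert res.stat[i] == pytest.approx(fit.tvalues[1], abs=1e-8)
            assert res.pvalues[i] == pytest.approx(fit.pvalues[1], abs=1e-8)

    def test_null_trait_calibrated(self):
        rng = np.random.default_rng(3)
        G = _geno(rng.integers(0, 3, size=(5000, 80)))
        y = rng.standard_normal(80)
        res = pa.pca_assoc(G, y)
        assert abs(pa.srmsd_p(res.pvalues)) < 0.01

    def test_collinear_locus_nan(self):
        rng = np.random.default_rng(4)
        X = rng.integers(0, 3, size=(2, 20)).astype(np.int8)
        X[1] = 1  # constant locus: collinear with intercept
        with pytest.warns(RuntimeWarning, match="collinear"):
            res = pa.pca_assoc(_geno(X), rng.standard_normal(20))
        assert np.isnan(res.pvalues[1]) and np.isfinite(res.pvalues[0])

    def test_rank_deficient_covariates_rejected(self, toy30):
        G, y, Z = toy30
        bad = np.column_stack([Z, Z[:, 0]])
        with pytest.raises(ValueError, match="rank deficient"):
            pa.pca_assoc(G, y, Z=bad)


class TestLmmNullReml:
    def test_pure_noise_boundary(self):
        """An unstructured trait on a sibship kinship: the genetic component
        hits the zero boundary and the residual absorbs Var(y).  (With Phi
        proportional to I the split would be unidentified.)"""
        blk = np.array([[0.5, 0.25], [0.25, 0.5]])
        phi = np.kron(np.eye(100), blk)
        rng = np.random.default_rng(1)
        y = rng.standard_normal(200) * 1.5
        vc = pa.lmm_null_reml(y, phi)
        assert vc.sigma_s2 == 0.0
        assert vc.sigma_e2 == pytest.approx(y.var(ddof=1), rel=0.05)

    def test_optimum_beats_dense_grid(self):
        """REML optimum vs an independent dense-matrix restricted likelihood
        evaluated on a (sigma_s2, sigma_e2) grid."""
        rng = np.random.default_rng(6)
        n = 25
        A = rng.standard_normal((n, 2 * n))
        phi = A @ A.T / (2 * n) / 2 + np.eye(n) * 0.1
        y = rng.multivariate_normal(np.zeros(n), 2 * 0.3 * phi + 0.7 * np.eye(n))
        X = np.ones((n, 1))
        vc = pa.lmm_null_reml(y, phi)

        def restricted_ll(ss, se):
            V = 2 * ss * phi + se * np.eye(n)
            Vi = np.linalg.inv(V)
            B = X.T @ Vi @ X
            P = Vi - Vi @ X @ np.linalg.inv(B) @ X.T @ Vi
            sign, ld_v = np.linalg.slogdet(V)
            sign2, ld_b = np.linalg.slogdet(B)
            return -0.5 * (ld_v + ld_b + y @ P @ y)

        best_fit = restricted_ll(vc.sigma_s2, vc.sigma_e2)
        grid = [
            restricted_ll(ss, se)
            for ss in np.linspace(0.01, 2.0, 10)
            for se in np.linspace(0.05, 2.0, 10)
        ]
        assert best_fit >= max(grid) - 1e-6

    def test_heritability_recovery(self):
        """REML variance components recover h2 = 0.8 across replicates.

        Uses the admixed-family simulation: family relatedness gives the
        kinship matrix a rich eigenvalue spectrum that identifies the
        genetic/residual split.  (Under the pure admixture kinship, which is
        approximately 0.5 I plus a rank-K smooth term, the split is weakly
        identified and per-replicate REML estimates are boundary-censored,
        so no estimator recovers it replicate-by-replicate.)"""
        from popassoc.data_io import filter_loci

        model = pa.fit_admixture_model(300, 10, 0.1, 0.5)
        rng = np.random.default_rng(17)
        ped = pa.draw_pedigree(model.coords, G=5, n=300, rng=rng)
        phi = pa.pedigree_kinship(
            ped, founder_coancestry=model.coancestry()
        )[-1]
        gvars, evars = [], []
        for _ in range(60):
            founder_G, freqs = pa.draw_admixture_genotypes(model, 2000,
                                                           rng=rng)
            G = pa.drop_genotypes(ped, founder_G, rng=rng)
            keep = G.maf() > 0
            tm, rep = pa.simulate_trait_replicate(
                filter_loci(G), h2=0.8, p_anc=freqs.p_anc[keep], m1=30,
                maf_min=0.0, rng=rng,
            )
            vc = pa.lmm_null_reml(rep.y, phi)
            gvars.append(vc.sigma_s2 * 2 * np.trace(phi) / 300)
            evars.append(vc.sigma_e2)
        g, e = np.mean(gvars), np.mean(evars)
        assert g / (g + e) == pytest.approx(0.8, abs=0.05)

    def test_asymmetric_kinship_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            pa.lmm_null_reml(np.zeros(3), np.array([[1, 0, 0], [0.5, 1, 0],
                                                    [0, 0, 1.0]]))


class TestLmmAssoc:
    def test_matches_dense_gls_oracle(self, toy30):
        """Score statistic vs brute-force dense-inverse projections."""
        G, y, Z = toy30
        rng = np.random.default_rng(8)
        A = rng.standard_normal((30, 60))
        phi = A @ A.T / 120 + np.eye(30) * 0.2
        vc = pa.VarianceComponents(sigma_s2=0.3, sigma_e2=0.7,
                                   log_restricted_likelihood=0.0, ratio=3 / 7)
        res = pa.lmm_assoc(G, y, phi, Z=Z, vc=vc)
        V = 2 * 0.3 * phi + 0.7 * np.eye(30)
        Vi = np.linalg.inv(V)
        X = np.column_stack([np.ones(30), Z])
        P = Vi - Vi @ X @ np.linalg.inv(X.T @ Vi @ X) @ X.T @ Vi
        for i in range(G.m):
            x = G.dosages[i].astype(float)
            expected = (x @ P @ y) ** 2 / (x @ P @ x)
            assert res.stat[i] == pytest.approx(expected, abs=1e-8)
            assert res.pvalues[i] == pytest.approx(
                stats.chi2.sf(expected, 1), abs=1e-10
            )

    def test_degenerate_kinship_matches_ols_score(self):
        """With Phi = I/2 and r=0 the score test collapses to the OLS score
        test; p-values then track the PCA t-test up to t-vs-chi2 tail
        differences that vanish with n."""
        rng = np.random.default_rng(9)
        n = 2000
        G = _geno(rng.integers(0, 3, size=(50, n)))
        y = rng.standard_normal(n)
        phi = np.eye(n) / 2
        res_lmm = pa.lmm_assoc(G, y, phi)
        # brute-force OLS score test with the REML null variance
        vc = res_lmm.variance_components
        sigma2 = vc.sigma_s2 + vc.sigma_e2  # V = sigma2 * I
        one = np.ones(n)
        yc = y - y.mean()
        for i in range(0, 50, 10):
            x = G.dosages[i].astype(float)
            xc = x - x.mean()
            expected = (xc @ yc) ** 2 / (xc @ xc) / sigma2
            assert res_lmm.stat[i] == pytest.approx(expected, rel=1e-8)
        res_pca = pa.pca_assoc(G, y)
        np.testing.assert_allclose(res_lmm.pvalues, res_pca.pvalues, atol=2e-3)

    def test_location_scale_invariance(self, toy30):
        G, y, Z = toy30
        rng = np.random.default_rng(10)
        A = rng.standard_normal((30, 60))
        phi = A @ A.T / 120 + np.eye(30) * 0.2
        res1 = pa.lmm_assoc(G, y, phi, Z=Z)
        res2 = pa.lmm_assoc(G, 3.0 + 2.5 * y, phi, Z=Z)
        np.testing.assert_allclose(res1.pvalues, res2.pvalues, atol=1e-8)

    def test_conservative_with_more_pcs(self):
        """On the admixture simulation, adding PCs to the LMM pushes signed
        SRMSDp down (conservative), never anti-conservative."""
        model = pa.fit_admixture_model(300, 10, 0.1, 0.5)
        rng = np.random.default_rng(11)
        G, freqs = pa.draw_admixture_genotypes(model, 10_000, rng=rng)
        tm, rep = pa.simulate_trait_replicate(G, h2=0.8, p_anc=freqs.p_anc,
                                              rng=rng)
        phi = pa.standard_kinship(G)
        null = np.ones(G.m, bool)
        null[tm.causal] = False
        U = pa.compute_pcs(G, 30)
        vals = []
        for r in (0, 10, 30):
            res = pa.lmm_assoc(G, rep.y, phi, U=U[:, :r] if r else None)
            vals.append(pa.srmsd_p(res.pvalues[null]))
        assert vals[0] < 0.01  # calibrated at r=0
        assert vals[2] < vals[0] + 0.003  # trend: not anti-conservative
        assert vals[2] < 0.005
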