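"""Whitening, marker scoring, pleiotropy test, thresholds, refinement."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from hirrm.association import (GenomeScan, bonferroni_threshold,
                               genomic_control, pleiotropy_test, score_marker,
                               whiten)
from hirrm.canonical import build_transform
from hirrm.genotypes import GenotypeMatrix, Kinship
from hirrm.simulate import SimulationConfig, simulate_dataset

from conftest import random_pd_pair
from test_varcomp import random_kinship


class TestWhiten:
    def test_zero_slambda_is_orthogonal(self, rng):
        kin = random_kinship(rng, 10)
        D = whiten(kin, 0.0)
        np.testing.assert_allclose(D @ D.T, np.eye(10), atol=1e-10)

    def test_negative_slambda_rejected(self, rng):
        with pytest.raises(ValueError, match="non-negative"):
            whiten(random_kinship(rng, 5), -0.1)

    def test_inverse_composition_recovers(self, rng):
        kin = random_kinship(rng, 8)
        D = whiten(kin, 0.7)
        y = rng.standard_normal(8)
        np.testing.assert_allclose(np.linalg.inv(D) @ (D @ y), y, atol=1e-10)

    def test_whitened_covariance_is_identity_mc(self, rng):
        n, lam, reps = 6, 0.9, 100_000
        kin = random_kinship(rng, n, m=40)
        V = lam * kin.matrix + np.eye(n)
        cv = np.linalg.cholesky(V)
        D = whiten(kin, lam)
        y = rng.standard_normal((reps, n)) @ cv.T
        z = y @ D.T
        np.testing.assert_allclose(np.cov(z.T), np.eye(n), atol=0.05)


class TestScoreMarker:
    def test_orthogonal_phenotype_scores_zero(self):
        z = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        eff, var, chi2 = score_marker(y, z)
        assert chi2 == 0.0

    def test_monomorphic_flagged(self):
        eff, var, chi2 = score_marker(np.ones(5), np.zeros(5))
        assert (eff, chi2) == (0.0, 0.0) and np.isinf(var)

    def test_matches_bruteforce_gls(self, rng):
        """Planted effect, n=30: EMMAX chi2 equals GLS with the full V."""
        n, lam = 30, 1.3
        kin = random_kinship(rng, n)
        z = rng.binomial(2, 0.4, n).astype(float)
        z -= z.mean()
        V = lam * kin.matrix + np.eye(n)
        y = 0.4 * z + np.linalg.cholesky(V) @ rng.standard_normal(n)
        X = np.ones((n, 1))
        D = whiten(kin, lam)
        yw, Xw, zw = D @ y, D @ X, D @ z
        q, _ = np.linalg.qr(Xw)
        yw = yw - q @ (q.T @ yw)
        zw = zw - q @ (q.T @ zw)
        eff, var, chi2 = score_marker(yw, zw)
        # brute force: GLS regression of y on [1, z] under covariance V
        Vinv = np.linalg.inv(V)
        Xf = np.column_stack([X, z])
        A = Xf.T @ Vinv @ Xf
        beta = np.linalg.solve(A, Xf.T @ Vinv @ y)
        cov = np.linalg.inv(A)
        chi2_gls = beta[1] ** 2 / cov[1, 1]
        assert chi2 == pytest.approx(chi2_gls, abs=1e-8)
        assert eff == pytest.approx(beta[1], abs=1e-8)

    def test_null_chi2_distribution(self, rng):
        """5000 null markers: whitened score is chi2_1 (KS test)."""
        n, m, lam = 400, 5000, 0.8
        kin = random_kinship(rng, n)
        V = lam * kin.matrix + np.eye(n)
        y = np.linalg.cholesky(V) @ rng.standard_normal(n)
        Z = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float)
        Z -= Z.mean(axis=0)
        D = whiten(kin, lam)
        yw = D @ y
        Xw = D @ np.ones((n, 1))
        q, _ = np.linalg.qr(Xw)
        yw = yw - q @ (q.T @ yw)
        Zw = D @ Z
        Zw -= q @ (q.T @ Zw)
        ztz = np.einsum("ij,ij->j", Zw, Zw)
        chi2 = (Zw.T @ yw) ** 2 / ztz
        # rescale: a single y realisation fixes the residual scale
        chi2 = chi2 / np.mean(chi2)
        p = stats.kstest(chi2, stats.chi2(df=1).cdf).pvalue
        assert p > 0.01


class TestPleiotropy:
    def test_all_zero(self):
        s, nl = pleiotropy_test(np.zeros(3))
        assert s == 0.0 and nl == pytest.approx(0.0, abs=1e-12)

    def test_quadrature_oracle(self):
        s, nl = pleiotropy_test(np.array([1.0, 2.0, 3.0]))
        tail, _ = integrate.quad(stats.chi2(df=3).pdf, 6.0, np.inf)
        assert s == 6.0
        assert nl == pytest.approx(-np.log10(tail), rel=1e-8)

    def test_null_mean_equals_df(self, rng):
        d = 4
        chi2 = rng.chisquare(1, size=(10_000, d))
        s, _ = pleiotropy_test(chi2)
        assert s.mean() == pytest.approx(d, abs=4 * np.sqrt(2 * d / 10_000))

    def test_underflow_capped(self):
        s, nl = pleiotropy_test(np.array([2000.0, 2000.0, 2000.0]))
        assert nl == 320.0


class TestThresholds:
    def test_mouse_panel_bonferroni(self):
        assert bonferroni_threshold(11833, 0.05) == pytest.approx(5.374, abs=5e-4)

    def test_single_marker(self):
        assert bonferroni_threshold(1, 0.05) == pytest.approx(1.301, abs=5e-4)

    def test_round_numbers(self):
        assert bonferroni_threshold(100, 1e-2) == pytest.approx(4.0, abs=1e-12)


class TestGenomicControl:
    def test_null_chi2_lambda_near_one(self, rng):
        chi2 = rng.chisquare(3, size=20_000)
        assert genomic_control(chi2, 3) == pytest.approx(1.0, abs=0.05)

    def test_scale_equivariance(self, rng):
        chi2 = rng.chisquare(3, size=1000)
        assert genomic_control(2 * chi2, 3) == pytest.approx(
            2 * genomic_control(chi2, 3), rel=1e-12)

    def test_too_few_markers_rejected(self, rng):
        with pytest.raises(ValueError, match="100"):
            genomic_control(rng.chisquare(3, size=50), 3)


class TestGenomeScan:
    def test_records_complete(self, small_dataset, small_null_fit):
        cc, reg, kin = small_null_fit
        scan = GenomeScan(reg, small_dataset.genotypes, kin, components=cc)
        res = scan.fit(refine=False)
        rec = res.records
        assert len(rec) == small_dataset.genotypes.n_markers
        for col in ("chrom", "snp", "pos", "maf", "chi2_sum", "neglog10_p"):
            assert col in rec.columns and rec[col].notna().all()
        np.testing.assert_allclose(
            rec["chi2_sum"], rec[["chi2_1", "chi2_2", "chi2_3"]].sum(axis=1),
            rtol=1e-10)
        assert res.threshold_neglog10 == pytest.approx(
            bonferroni_threshold(small_dataset.genotypes.n_markers, 0.05))
        assert res.df == 3

    def test_summed_chi2_equals_bruteforce_mvgls(self, rng):
        """n=25, d=2: summed per-trait chi2 equals the multivariate Wald
        statistic from GLS with V = S_lambda x K + I."""
        n, d = 25, 2
        kin = random_kinship(rng, n)
        Vg, Vpe = random_pd_pair(rng, d)
        t = build_transform(Vg, Vpe)
        cg, cp = np.linalg.cholesky(Vg), np.linalg.cholesky(Vpe)
        ck = np.linalg.cholesky(kin.matrix + 1e-10 * np.eye(n))
        P = ck @ rng.standard_normal((n, d)) @ cg.T \
            + rng.standard_normal((n, d)) @ cp.T
        z = rng.binomial(2, 0.3, n).astype(float)
        P_star = P @ t.L.T
        # package route: whiten each pseudo-trait, residualize intercept
        chi2_sum = 0.0
        zc = z - z.mean()
        for l in range(d):
            D = whiten(kin, t.s_lambda[l])
            yw = D @ P_star[:, l]
            Xw = D @ np.ones((n, 1))
            q, _ = np.linalg.qr(Xw)
            yw = yw - q @ (q.T @ yw)
            zw = D @ zc
            zw = zw - q @ (q.T @ zw)
            chi2_sum += score_marker(yw, zw)[2]
        # oracle: full multivariate GLS on the transformed scale
        V = np.kron(np.diag(t.s_lambda), kin.matrix) + np.eye(n * d)
        Vinv = np.linalg.inv(V)
        y_vec = P_star.T.ravel()  # trait-major stacking
        Xf = np.column_stack([
            np.kron(np.eye(d), np.ones((n, 1))),
            np.kron(np.eye(d), zc[:, None]),
        ])
        A = Xf.T @ Vinv @ Xf
        beta = np.linalg.solve(A, Xf.T @ Vinv @ y_vec)
        cov = np.linalg.inv(A)
        a_hat = beta[d:]
        wald = a_hat @ np.linalg.solve(cov[d:, d:], a_hat)
        assert chi2_sum == pytest.approx(wald, abs=1e-6)

    def test_effect_concentration_on_perturbed_parameter(self, rng):
        """A QTL acting on the asymptote alone back-transforms onto the
        asymptote component."""
        n, d, reps = 300, 3, 12
        Vg = np.eye(d)
        Vpe = np.eye(d) + 0.5 - 0.5 * np.eye(d)
        effs = []
        for rep in range(reps):
            r2 = np.random.default_rng(500 + rep)
            kin = Kinship(np.eye(n), [f"i{i}" for i in range(n)])
            z = r2.binomial(2, 0.4, n).astype(float)
            P = r2.standard_normal((n, d)) @ np.linalg.cholesky(Vg + Vpe).T
            P[:, 0] += 0.8 * z  # effect on trait "a" only
            t = build_transform(Vg, Vpe)
            markers = pd.DataFrame({
                "chrom": "1", "snp": ["q"], "cm": 0.0, "pos": [100],
                "a1": "A", "a2": "B"})
            g = GenotypeMatrix(z[:, None], markers, kin.ids)
            res = GenomeScan(P, g, kin, transform=t,
                             trait_names=("a", "b", "r")).fit(refine=False)
            effs.append(res.records[["effect_a", "effect_b", "effect_r"]]
                        .to_numpy()[0])
        effs = np.asarray(effs)
        mean, se = effs.mean(0), effs.std(0, ddof=1) / np.sqrt(reps)
        assert abs(mean[0] - 0.8) < 3 * se[0] + 0.02
        assert abs(mean[1]) < 3 * se[1] + 0.02
        assert abs(mean[2]) < 3 * se[2] + 0.02


class TestRefinement:
    def test_no_suggestive_markers_single_round(self, rng):
        n, m = 80, 120
        kin = random_kinship(rng, n)
        P = rng.standard_normal((n, 2))
        counts = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        markers = pd.DataFrame({
            "chrom": "1", "snp": [f"s{j}" for j in range(m)], "cm": 0.0,
            "pos": np.arange(m) * 10 + 1, "a1": "A", "a2": "B"})
        g = GenotypeMatrix(counts, markers, kin.ids)
        t = build_transform(np.eye(2), np.eye(2))
        res = GenomeScan(P, g, kin, transform=t).fit(
            refine=True, suggestive_p=1e-300, suggestive_top_frac=0.0)
        assert res.rounds_used == 1
        assert not res.records["refined"].any()

    def test_duplicate_marker_refined_identically(self, rng):
        n, m = 100, 60
        kin = random_kinship(rng, n)
        counts = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        counts[:, 31] = counts[:, 30]  # exact duplicate
        P = rng.standard_normal((n, 1))
        P[:, 0] += 1.2 * counts[:, 30]
        markers = pd.DataFrame({
            "chrom": "1", "snp": [f"s{j}" for j in range(m)], "cm": 0.0,
            "pos": np.arange(m) * 10 + 1, "a1": "A", "a2": "B"})
        g = GenotypeMatrix(counts, markers, kin.ids)
        t = build_transform(np.eye(1), np.eye(1))
        res = GenomeScan(P, g, kin, transform=t).fit(refine=True)
        rec = res.records
        assert rec["refined"].iloc[30] and rec["refined"].iloc[31]
        assert rec["chi2_sum"].iloc[30] == rec["chi2_sum"].iloc[31]
        assert res.rounds_used == 2

    def test_refinement_raises_mean_chi2_at_planted_qtl(self):
        """The EMMAX approximation loses power at strong QTLs; the exact
        re-test recovers it on average."""
        diffs = []
        for rep in range(6):
            rng = np.random.default_rng(900 + rep)
            n, m = 150, 150
            kin = random_kinship(rng, n)
            counts = rng.binomial(2, rng.uniform(0.2, 0.5, m),
                                  size=(n, m)).astype(float)
            z = counts[:, 75]
            ck = np.linalg.cholesky(kin.matrix + 1e-8 * np.eye(n))
            P = (1.0 * (z - z.mean()) + ck @ rng.standard_normal(n)
                 + rng.standard_normal(n))[:, None]
            markers = pd.DataFrame({
                "chrom": "1", "snp": [f"s{j}" for j in range(m)], "cm": 0.0,
                "pos": np.arange(m) * 10 + 1, "a1": "A", "a2": "B"})
            g = GenotypeMatrix(counts, markers, kin.ids)
            # deliberately inflated genome-wide ratio, as a strong QTL causes
            t = build_transform(np.array([[3.0]]), np.array([[1.0]]))
            scan = GenomeScan(P, g, kin, transform=t)
            r1 = scan.fit(refine=False)
            r2 = scan.fit(refine=True, suggestive_p=1e-3)
            diffs.append(r2.records["chi2_sum"].iloc[75]
                         - r1.records["chi2_sum"].iloc[75])
        assert np.mean(diffs) > 0
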