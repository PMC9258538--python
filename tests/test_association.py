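"""Kinship LMM, single-SNP scan, stepwise multi-locus, spike-and-slab, PVE.

The scan and spike-and-slab are checked against independent oracles: direct
GLS with the full covariance matrix, and exhaustive Bayesian model averaging
(computable in closed form for one or two predictors).
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import multivariate_normal

import panelgwas as pg


def _panel(n, P, seed, **kw):
    cfg = pg.SimulationConfig(n_genotypes=n, n_snps=P,
                              n_chromosomes=kw.pop("n_chromosomes", 2),
                              seed=seed, **kw)
    return pg.simulate_genotypes(cfg)


class TestKinshipLMM:
    def test_identity_kinship_matches_ordinary_partition(self, rng):
        # with A = Id the model is y = mu + u + e with u, e both iid: only
        # the total variance is identified, and a pure-noise response puts
        # essentially nothing on the polygenic term relative to the total
        y = rng.normal(size=150)
        fit = pg.fit_null_lmm(y, np.eye(150))
        total = fit.sigma2_u + fit.sigma2_e
        assert total == pytest.approx(np.var(y, ddof=1), rel=0.05)

    def test_variance_ratio_recovery(self):
        gm = _panel(250, 400, seed=61)
        A = pg.kinship_additive(gm)
        L = np.linalg.cholesky(A + 1e-8 * np.eye(250))
        rng = np.random.default_rng(8)
        ratios = []
        for _ in range(30):
            y = (L @ rng.standard_normal(250)) * np.sqrt(0.5) \
                + rng.standard_normal(250) * np.sqrt(0.5)
            ratios.append(pg.fit_null_lmm(y, A).heritability_ratio)
        assert np.mean(ratios) == pytest.approx(0.5, abs=0.05)

    def test_constant_response_handled(self):
        fit = pg.fit_null_lmm(np.ones(50), np.eye(50))
        assert fit.sigma2_u == 0.0 and fit.sigma2_e == 0.0


class TestScanSingleSnp:
    def test_matches_direct_gls_oracle(self, rng):
        # brute-force GLS with the full covariance on a small instance
        gm = _panel(18, 40, seed=62)
        A = pg.kinship_additive(gm)
        y = rng.normal(size=18)
        scan = pg.scan_single_snp(y, gm, A)
        null = scan.null_fit
        V = null.sigma2_u * A + null.sigma2_e * np.eye(18)
        Vi = np.linalg.inv(V)
        G = gm.imputed()
        for j in range(40):
            x = G[:, j]
            if np.var(x) < 1e-12:
                continue
            X = np.column_stack([np.ones(18), x])
            C = np.linalg.inv(X.T @ Vi @ X)
            b = C @ X.T @ Vi @ y
            assert scan.table["beta"][j] == pytest.approx(b[1], abs=1e-8)
            assert scan.table["se"][j] == pytest.approx(np.sqrt(C[1, 1]), abs=1e-8)

    def test_exact_mode_agrees_on_strong_signal(self, rng):
        gm = _panel(60, 25, seed=63)
        A = pg.kinship_additive(gm)
        x = gm.imputed()[:, 3]
        y = x * 1.0 + rng.normal(size=60) * 0.5
        approx = pg.scan_single_snp(y, gm, A)
        exact = pg.scan_single_snp(y, gm, A, exact=True)
        j = 3
        assert exact.table["beta"][j] == pytest.approx(approx.table["beta"][j], rel=0.1)
        assert exact.table["pvalue"][j] < approx.bonferroni_threshold

    def test_bonferroni_threshold_is_alpha_over_p(self):
        gm = _panel(40, 100, seed=64)
        A = pg.kinship_additive(gm)
        scan = pg.scan_single_snp(np.random.default_rng(0).normal(size=40), gm, A)
        assert scan.bonferroni_threshold == pytest.approx(0.05 / 100)

    def test_monomorphic_snp_flagged_not_significant(self, rng):
        gm = _panel(50, 20, seed=65)
        vals = gm.values.copy()
        vals[:, 5] = 2.0
        gm2 = pg.GenotypeMatrix(vals, gm.sample_ids, gm.markers)
        scan = pg.scan_single_snp(rng.normal(size=50), gm2, pg.kinship_additive(gm2))
        assert scan.table["beta"][5] == 0.0
        assert scan.table["pvalue"][5] == 1.0
        assert not scan.table["significant"][5]

    def test_null_pvalues_uniform_with_kinship_structure(self):
        gm = _panel(150, 1500, seed=66, n_chromosomes=3)
        A = pg.kinship_additive(gm, ld_prune_r2=0.5)
        L = np.linalg.cholesky(A + 1e-8 * np.eye(150))
        rng = np.random.default_rng(9)
        pv = []
        for _ in range(10):
            y = (L @ rng.standard_normal(150)) * np.sqrt(0.5) \
                + rng.standard_normal(150) * np.sqrt(0.5)
            pv.append(pg.scan_single_snp(y, gm, A).table["pvalue"].to_numpy())
        pv = np.concatenate(pv)
        assert 0.03 <= (pv < 0.05).mean() <= 0.07
        assert stats.kstest(pv, "uniform").statistic < 0.03


class TestStepwise:
    def test_null_response_selects_empty_model(self):
        gm = _panel(120, 400, seed=67)
        A = pg.kinship_additive(gm)
        rng = np.random.default_rng(10)
        empty = 0
        for _ in range(10):
            fit = pg.stepwise_mlmm(rng.normal(size=120), gm, A)
            empty += len(fit.cofactors) == 0
        assert empty >= 9

    def test_three_planted_qtls_recovered(self):
        gm = _panel(250, 600, seed=68, n_chromosomes=3)
        A = pg.kinship_additive(gm)
        W = gm.imputed()
        W = W - W.mean(0)
        rng = np.random.default_rng(11)
        hits = 0
        n_sim = 8
        for s in range(n_sim):
            idx = rng.choice(600, 3, replace=False)
            g = sum(W[:, j] / W[:, j].std() for j in idx)
            y = g * np.sqrt(0.15) + rng.normal(size=250) * np.sqrt(1 - 3 * 0.15)
            fit = pg.stepwise_mlmm(y, gm, A)
            found = 0
            for j in idx:
                x = W[:, j]
                for cid in fit.cofactors:
                    k = gm.markers.index[gm.markers["id"] == cid][0]
                    if np.corrcoef(x, W[:, k])[0, 1] ** 2 > 0.5:
                        found += 1
                        break
            hits += found == 3
        assert hits >= 0.8 * n_sim

    def test_path_truncates_at_max_iter(self):
        gm = _panel(80, 60, seed=69)
        A = pg.kinship_additive(gm)
        W = gm.imputed()
        rng = np.random.default_rng(12)
        # many huge independent effects keep the polygenic ratio high
        y = W @ rng.normal(0, 1.0, 60)
        fit = pg.stepwise_mlmm(y, gm, A, max_iter=7, h2_stop=1e-12)
        assert len(fit.path) <= 7

    def test_collinear_cofactor_skipped(self):
        gm = _panel(60, 10, seed=70)
        vals = gm.values.copy()
        vals[:, 1] = vals[:, 0]  # perfect duplicate
        gm2 = pg.GenotypeMatrix(vals, gm.sample_ids, gm.markers)
        A = pg.kinship_additive(gm2)
        y = vals[:, 0] * 2.0 + np.random.default_rng(1).normal(size=60) * 0.3
        fit = pg.stepwise_mlmm(y, gm2, A, max_iter=4)
        assert not ({"s0", "s1"} <= set(fit.path))  # never both copies


class TestSpikeSlab:
    def test_p1_matches_exact_bayes_factor(self, rng):
        n = 100
        x = rng.normal(size=(n, 1))
        x -= x.mean()
        for b, pi in [(1.0, 0.1), (0.0, 0.3), (0.15, 0.2)]:
            y = x[:, 0] * b + rng.normal(size=n) * 0.5
            sigma2, sb2 = 0.25, 1.0
            fit = pg.spike_slab_fit(y, x, pi_grid=[pi], slab_var=sb2, sigma2=sigma2)
            yc = y - y.mean()
            l0 = multivariate_normal.logpdf(yc, cov=sigma2 * np.eye(n))
            l1 = multivariate_normal.logpdf(
                yc, cov=sigma2 * np.eye(n) + sb2 * np.outer(x[:, 0], x[:, 0])
            )
            bf = np.exp(l1 - l0)
            exact = pi * bf / (pi * bf + 1 - pi)
            assert float(fit.pip.iloc[0]) == pytest.approx(exact, abs=0.02)

    def test_p2_orthogonal_matches_model_averaging(self, rng):
        n = 120
        x1 = rng.normal(size=n)
        x1 -= x1.mean()
        x2 = rng.normal(size=n)
        x2 -= x2.mean()
        x2 -= x1 * (x1 @ x2) / (x1 @ x1)
        X = np.column_stack([x1, x2])
        sigma2, sb2, pi = 0.36, 0.25, 0.2
        y = 0.3 * x1 + rng.normal(size=n) * 0.6
        fit = pg.spike_slab_fit(y, X, pi_grid=[pi], slab_var=sb2, sigma2=sigma2)
        yc = y - y.mean()
        logps, incl = [], []
        for inc in itertools.product([0, 1], repeat=2):
            C = sigma2 * np.eye(n)
            for k, z in enumerate(inc):
                if z:
                    C = C + sb2 * np.outer(X[:, k], X[:, k])
            lp = multivariate_normal.logpdf(yc, cov=C) \
                + sum(np.log(pi) if z else np.log(1 - pi) for z in inc)
            logps.append(lp)
            incl.append(inc)
        w = np.exp(np.array(logps) - max(logps))
        w /= w.sum()
        for k in range(2):
            exact = sum(w[i] for i, inc in enumerate(incl) if inc[k])
            assert float(fit.pip.iloc[k]) == pytest.approx(exact, abs=0.05)

    def test_overwhelming_single_snp_pip_near_one(self, rng):
        n = 150
        x = rng.normal(size=(n, 1))
        y = x[:, 0] * 2.0 + rng.normal(size=n) * 0.3  # t-stat >> 10
        fit = pg.spike_slab_fit(y, x, pi_grid=[0.1], slab_var=4.0, sigma2=0.09)
        assert float(fit.pip.iloc[0]) > 0.99

    def test_null_response_pips_low(self):
        gm = _panel(150, 500, seed=71)
        rng = np.random.default_rng(13)
        ok = 0
        for _ in range(8):
            fit = pg.spike_slab_fit(rng.normal(size=150), gm, n_grid=8)
            ok += (fit.pip < 0.5).all()
        assert ok >= 7

    def test_elbo_increases_along_grid_iterations(self, rng):
        gm = _panel(100, 200, seed=72)
        x = gm.imputed()[:, 10]
        y = x + rng.normal(size=100) * 0.7
        fit = pg.spike_slab_fit(y, gm, n_grid=10)
        assert np.isfinite(fit.hyper_grid["elbo"]).all()
        assert fit.hyper_grid["weight"].sum() == pytest.approx(1.0)

    def test_importance_weights_concentrate_sensibly(self, rng):
        # a clearly sparse signal should not put all weight on pi ~ 0.5
        gm = _panel(150, 300, seed=73)
        W = gm.imputed()
        y = W[:, 5] * 1.0 + rng.normal(size=150) * 0.5
        fit = pg.spike_slab_fit(y, gm, n_grid=10)
        top = fit.hyper_grid.sort_values("weight").iloc[-1]
        assert top["pi0"] < 0.2


class TestTopSignalAgreement:
    def test_methods_agree_on_dominant_qtl(self):
        gm = _panel(200, 800, seed=74, n_chromosomes=4)
        A = pg.kinship_additive(gm)
        W = gm.imputed()
        Wc = W - W.mean(0)
        rng = np.random.default_rng(14)
        agree = 0
        n_sim = 6
        for _ in range(n_sim):
            j = rng.integers(0, 800)
            x = Wc[:, j]
            y = x / x.std() * np.sqrt(0.3) + rng.normal(size=200) * np.sqrt(0.7)
            scan = pg.scan_single_snp(y, gm, A)
            top_scan = int(np.argmin(scan.table["pvalue"].to_numpy()))
            sw = pg.stepwise_mlmm(y, gm, A, max_iter=3)
            ss = pg.spike_slab_fit(y, gm, n_grid=8)
            top_ss = int(np.argmax(ss.pip.to_numpy()))
            ids = list(gm.markers["id"])
            picks = [top_scan, ids.index(sw.path[0]), top_ss]
            r2 = [np.corrcoef(Wc[:, a], Wc[:, b])[0, 1] ** 2
                  for a, b in itertools.combinations(picks, 2)]
            agree += min(r2) > 0.8
        assert agree >= 0.8 * n_sim


class TestEstimatePve:
    def test_recovery_at_known_ratios(self):
        gm = _panel(250, 500, seed=75)
        A = pg.kinship_additive(gm, ld_prune_r2=0.5)
        L = np.linalg.cholesky(A + 1e-8 * np.eye(250))
        rng = np.random.default_rng(15)
        for ratio in (0.0, 0.5, 0.8):
            ests = []
            for _ in range(20):
                y = (L @ rng.standard_normal(250)) * np.sqrt(ratio) \
                    + rng.standard_normal(250) * np.sqrt(1 - ratio)
                ests.append(pg.estimate_pve(y, A).pve_snps)
            assert np.mean(ests) == pytest.approx(ratio, abs=0.1)

    def test_additive_dominance_model_reports_identifiability(self):
        gm = _panel(200, 800, seed=76, n_chromosomes=4)
        A = pg.kinship_additive(gm, ld_prune_r2=0.5)
        D = pg.kinship_dominance(gm, ld_prune_r2=0.5)
        rng = np.random.default_rng(16)
        L = np.linalg.cholesky(A + 1e-8 * np.eye(200))
        y = (L @ rng.standard_normal(200)) * np.sqrt(0.5) \
            + rng.standard_normal(200) * np.sqrt(0.5)
        add_only = pg.estimate_pve(y, A)
        both = pg.estimate_pve(y, A, D=D)
        assert both.identifiability_warning is not None  # D ~ identity
        # sigma2_a is stable whether or not the weakly-identified dominance
        # term is in the model
        assert both.sigma2_a == pytest.approx(add_only.sigma2_a, rel=0.15, abs=0.02)

    def test_bootstrap_ci_contains_point_estimate(self):
        gm = _panel(120, 300, seed=77)
        A = pg.kinship_additive(gm, ld_prune_r2=0.5)
        rng = np.random.default_rng(17)
        L = np.linalg.cholesky(A + 1e-8 * np.eye(120))
        y = (L @ rng.standard_normal(120)) * np.sqrt(0.6) \
            + rng.standard_normal(120) * np.sqrt(0.4)
        dec = pg.estimate_pve(y, A, n_boot=40, seed=3)
        assert dec.ci_low <= dec.pve_snps <= dec.ci_high
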