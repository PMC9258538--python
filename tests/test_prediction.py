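"""Genomic prediction: ridge/GBLUP identity, CV assessment, out-of-population
prediction and architecture classification."""

import numpy as np
import pandas as pd
import pytest

import panelgwas as pg
from panelgwas.prediction import _assess_fold


def _panel(n, P, seed):
    cfg = pg.SimulationConfig(n_genotypes=n, n_snps=P, n_chromosomes=2, seed=seed)
    return pg.simulate_genotypes(cfg)


def _trait(gm, arch, h2, n_causal, seed):
    rng = np.random.default_rng(seed)
    W = gm.imputed()
    W = W - W.mean(0)
    k = n_causal if arch == "sparse" else gm.n_snps
    idx = rng.choice(gm.n_snps, k, replace=False)
    g = W[:, idx] @ rng.normal(size=k)
    g = g / g.std() * np.sqrt(h2)
    return g + rng.normal(0, np.sqrt(1 - h2), gm.n_samples)


class TestRidgeGblupIdentity:
    def test_primal_ridge_equals_dual_gblup(self, rng):
        gm = _panel(70, 300, seed=81)
        y = _trait(gm, "dense", 0.5, None, 1)
        model = pg.fit_ridge(y, gm)
        M = gm.imputed()
        p = M.mean(0) / 2
        W = M - 2 * p
        c = 2 * np.sum(p * (1 - p))
        lam = model.sigma2_e_ / (model.sigma2_a_ / c)
        beta = np.linalg.solve(W.T @ W + lam * np.eye(W.shape[1]),
                               W.T @ (y - model.mu_))
        fitted_primal = model.mu_ + W @ beta
        np.testing.assert_allclose(
            fitted_primal, model.fitted_values_,
            rtol=1e-6, atol=1e-6 * np.std(y),
        )

    def test_zero_signal_predicts_training_mean(self, rng):
        gm = _panel(100, 200, seed=82)
        y = np.full(100, 3.7) + rng.normal(size=100) * 1e-8
        model = pg.fit_ridge(y[:80], gm.take_samples(np.arange(80)))
        pred = model.predict(gm.take_samples(np.arange(80, 100)))
        np.testing.assert_allclose(pred, 3.7, atol=1e-4)

    def test_missing_test_markers_fatal(self):
        gm = _panel(40, 50, seed=83)
        model = pg.fit_ridge(np.random.default_rng(0).normal(size=40), gm)
        sub = gm.take_snps(np.arange(10))
        with pytest.raises(ValueError, match="training markers"):
            model.predict(sub)


class TestAssessment:
    def test_oracle_predictions_perfect_metrics(self, rng):
        obs = rng.normal(size=60)
        row = _assess_fold(obs, obs.copy())
        assert row["rmse"] == pytest.approx(0.0, abs=1e-12)
        assert row["corP"] == pytest.approx(1.0)
        assert row["slope"] == pytest.approx(1.0)
        assert row["intercept"] == pytest.approx(0.0, abs=1e-10)
        assert row["bias_pvalue"] == pytest.approx(1.0)

    def test_cv_reproducible_under_seed(self):
        gm = _panel(80, 200, seed=84)
        y = _trait(gm, "dense", 0.5, None, 2)
        a = pg.cross_validate(y, gm, method="ridge", k=5, repeats=2, seed=11)
        b = pg.cross_validate(y, gm, method="ridge", k=5, repeats=2, seed=11)
        pd.testing.assert_frame_equal(a.per_fold, b.per_fold)

    def test_k_larger_than_n_fatal(self):
        gm = _panel(10, 50, seed=85)
        with pytest.raises(ValueError, match="exceeds"):
            pg.cross_validate(np.zeros(10), gm, k=20)

    def test_accuracy_bounded_by_root_heritability(self):
        gm = _panel(200, 800, seed=86)
        h2 = 0.7
        cors = []
        for s in range(3):
            y = _trait(gm, "dense", h2, None, 10 + s)
            cv = pg.cross_validate(y, gm, method="ridge", k=5, repeats=1, seed=s)
            cors.append(cv.corP)
        assert np.mean(cors) <= np.sqrt(h2) + 0.1

    def test_corS_invariant_under_monotone_transform_of_predictions(self, rng):
        obs = rng.normal(size=50)
        pred = obs + rng.normal(size=50)
        a = _assess_fold(obs, pred)
        b = _assess_fold(obs, np.exp(pred / 2.0))  # monotone
        c = _assess_fold(obs, 3.0 * pred + 1.0)    # positive affine
        assert a["corS"] == pytest.approx(b["corS"])
        assert a["corP"] == pytest.approx(c["corP"])

    def test_label_shuffling_destroys_accuracy(self):
        gm = _panel(150, 300, seed=87)
        y = _trait(gm, "dense", 0.6, None, 3)
        model = pg.fit_ridge(y, gm)
        pred = model.fitted_values_
        rng = np.random.default_rng(4)
        cors = [
            _assess_fold(rng.permutation(y), pred)["corP"] for _ in range(100)
        ]
        assert abs(np.mean(cors)) < 0.05

    def test_accuracy_grows_with_training_size(self):
        gm = _panel(250, 600, seed=88)
        y = _trait(gm, "dense", 0.6, None, 5)
        small, large = [], []
        rng = np.random.default_rng(6)
        for _ in range(8):
            test = rng.choice(250, 50, replace=False)
            rest = np.setdiff1d(np.arange(250), test)
            for size, store in ((100, small), (200, large)):
                tr = rng.choice(rest, size, replace=False)
                m = pg.fit_ridge(y[tr], gm.take_samples(tr))
                store.append(
                    _assess_fold(y[test], m.predict(gm.take_samples(test)))["corP"]
                )
        assert np.mean(large) > np.mean(small) - 0.02


class TestSparseVsDense:
    def test_sparse_predictor_wins_on_sparse_trait(self):
        gm = _panel(180, 700, seed=89)
        wins = 0
        n_rounds = 0
        for s in range(4):
            y = _trait(gm, "sparse", 0.8, 3, 20 + s)
            r = pg.cross_validate(y, gm, method="ridge", k=5, repeats=1, seed=s)
            v = pg.cross_validate(y, gm, method="ssvs", k=5, repeats=1, seed=s)
            for (_, a), (_, b) in zip(r.per_fold.iterrows(), v.per_fold.iterrows()):
                wins += b["corS"] >= a["corS"]
                n_rounds += 1
        assert wins / n_rounds >= 0.7

    def test_ridge_wins_on_dense_trait(self):
        gm = _panel(180, 700, seed=90)
        wins = 0
        n_rounds = 0
        for s in range(4):
            y = _trait(gm, "dense", 0.8, None, 30 + s)
            r = pg.cross_validate(y, gm, method="ridge", k=5, repeats=1, seed=s)
            v = pg.cross_validate(y, gm, method="ssvs", k=5, repeats=1, seed=s)
            for (_, a), (_, b) in zip(r.per_fold.iterrows(), v.per_fold.iterrows()):
                wins += a["corS"] >= b["corS"]
                n_rounds += 1
        assert wins / n_rounds >= 0.7

    def test_null_trait_accuracy_centered_on_zero(self):
        gm = _panel(120, 300, seed=91)
        rng = np.random.default_rng(7)
        cors = {"ridge": [], "ssvs": []}
        for s in range(6):
            y = rng.normal(size=120)
            for m in cors:
                cv = pg.cross_validate(y, gm, method=m, k=4, repeats=1, seed=s)
                cors[m].extend(cv.per_fold["corP"].dropna().tolist())
        for m, v in cors.items():
            assert abs(np.mean(v)) < 0.12


class TestOutOfPopulation:
    def _progeny(self, gm, n_off, seed):
        """F1s of two panel members: gametes sample one parental allele."""
        rng = np.random.default_rng(seed)
        i, j = rng.choice(gm.n_samples, 2, replace=False)
        pa, pb = gm.values[i], gm.values[j]
        def gamete(par, size):
            # transmit one allele: dosage/2 chance of alt per locus
            return (rng.random((size, gm.n_snps)) < par / 2.0).astype(float)
        off = gamete(pa, n_off) + gamete(pb, n_off)
        return pg.GenotypeMatrix(off, [f"F1_{k}" for k in range(n_off)],
                                 gm.markers.copy())

    def test_marker_intersection_and_assessment(self):
        gm = _panel(150, 400, seed=92)
        y = _trait(gm, "dense", 0.6, None, 8)
        prog = self._progeny(gm, 30, seed=9)
        W = gm.imputed().mean(0)
        # progeny trait from the same marker effects is not reconstructible
        # here; just check plumbing and the ridge-beats-sparse direction
        rng = np.random.default_rng(10)
        # rebuild a dense trait with shared effects for panel and progeny
        Wp = gm.imputed() - W
        Wo = prog.imputed() - W
        beta = rng.normal(size=gm.n_snps) * 0.05
        yp = Wp @ beta
        yp = yp / yp.std()
        yo = Wo @ beta / (Wp @ beta).std()
        yp_n = yp * np.sqrt(0.6) + rng.normal(size=150) * np.sqrt(0.4)
        yo_n = yo * np.sqrt(0.6) + rng.normal(size=30) * np.sqrt(0.4)
        res_r = pg.predict_out_of_population(yp_n, gm, yo_n, prog, method="ridge")
        res_s = pg.predict_out_of_population(yp_n, gm, yo_n, prog, method="ssvs")
        assert res_r.corP > 0.2
        assert res_r.corP >= res_s.corP - 0.15

    def test_too_few_shared_markers_fatal(self):
        gm = _panel(40, 50, seed=93)
        other = gm.take_snps(np.arange(5))
        with pytest.raises(ValueError, match="overlapping markers"):
            pg.predict_out_of_population(
                np.zeros(40), gm, np.zeros(40), other
            )

    def test_training_subset_predicts_at_least_as_well_as_cv(self):
        gm = _panel(150, 400, seed=94)
        y = _trait(gm, "dense", 0.6, None, 12)
        cv = pg.cross_validate(y, gm, method="ridge", k=5, repeats=1, seed=1)
        sub = np.arange(30)
        res = pg.predict_out_of_population(
            y, gm, y[sub], gm.take_samples(sub), method="ridge"
        )
        assert res.corP >= cv.corP - 0.05  # information reuse helps


class TestClassifyArchitecture:
    def test_uniform_positive_deltas_high_confidence_sparse(self):
        cors_s = pd.Series({f"t{i}": 0.5 + 0.05 for i in range(5)})
        cors_d = pd.Series({f"t{i}": 0.5 for i in range(5)})
        calls = pg.classify_architecture(
            cors_s, cors_d, {f"t{i}": "classA" for i in range(5)}
        )
        assert len(calls) == 1
        c = calls[0]
        assert c.call == "sparse" and c.confidence == "high"
        assert c.median_delta == pytest.approx(0.05)

    def test_symmetric_deltas_low_confidence(self):
        deltas = [-0.2, -0.1, 0.0, 0.1, 0.2]
        cors_s = pd.Series({f"t{i}": 0.4 + d for i, d in enumerate(deltas)})
        cors_d = pd.Series({f"t{i}": 0.4 for i in range(5)})
        calls = pg.classify_architecture(
            cors_s, cors_d, {f"t{i}": "c" for i in range(5)}
        )
        assert abs(calls[0].median_delta) < 1e-12
        assert calls[0].confidence == "low"

    def test_empty_class_skipped_with_warning(self):
        cors = pd.Series({"t0": 0.5})
        with pytest.warns(UserWarning, match="skipped"):
            calls = pg.classify_architecture(
                cors, cors, pd.Series({"t0": "a", "missing": "b"})
            )
        assert [c.trait_class for c in calls] == ["a"]
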