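"""Elastic-net cis models, windows, transfer and the lead-eQTL alternative."""

import inspect

import numpy as np
import pandas as pd
import pytest

import vset_interact as vi
from vset_interact.cis import cis_window, evaluate_transfer, fit_cis_model, lead_eqtl


def cd_elastic_net(X, y, alpha, l1_ratio, tol=1e-12, max_iter=50_000):
    """Independent coordinate-descent oracle for the elastic-net problem

    (1/2n)||y - Xw - b||^2 + alpha*l1*||w||_1 + (alpha*(1-l1)/2)*||w||^2
    """
    n, p = X.shape
    w = np.zeros(p)
    b = y.mean() - X.mean(axis=0) @ w
    z = (X**2).sum(axis=0) / n
    for _ in range(max_iter):
        w_old = w.copy()
        r = y - X @ w - b
        for j in range(p):
            r += X[:, j] * w[j]
            rho = X[:, j] @ r / n
            w[j] = np.sign(rho) * max(abs(rho) - alpha * l1_ratio, 0.0) / (
                z[j] + alpha * (1 - l1_ratio)
            )
            r -= X[:, j] * w[j]
        b = y.mean() - X.mean(axis=0) @ w
        if np.max(np.abs(w - w_old)) < tol:
            break
    return w, b


def _standardised_problem(rng, n=80, p=5, noise=0.5):
    X = rng.normal(size=(n, p))
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    beta = np.array([1.0, -0.5, 0.0, 0.8, 0.0])[:p]
    y = X @ beta + noise * rng.normal(size=n)
    return X, y


class TestCisWindow:
    SNPS = pd.DataFrame(
        {
            "chrom": ["chr1"] * 4,
            "pos": [3_999_999, 4_000_000, 6_050_000, 6_050_001],
        },
        index=["s1", "s2", "s3", "s4"],
    )

    def test_one_megabase_margins(self):
        ann = {"gene": "g", "chrom": "chr1", "tss": 5_000_000, "tes": 5_050_000}
        win = cis_window(ann, self.SNPS)
        assert (win.start, win.end) == (4_000_000, 6_050_000)
        # boundary SNPs at exactly TSS-1Mb and TES+1Mb are included
        assert win.snp_ids == ["s2", "s3"]

    def test_start_clipped_at_one(self):
        ann = {"gene": "g", "chrom": "chr1", "tss": 400_000, "tes": 450_000}
        assert cis_window(ann, self.SNPS).start == 1

    def test_missing_chromosome_rejected(self):
        ann = {"gene": "g", "chrom": "chrX", "tss": 1, "tes": 2}
        with pytest.raises(ValueError, match="chrX"):
            cis_window(ann, self.SNPS)

    def test_tss_after_tes_rejected(self):
        ann = {"gene": "g", "chrom": "chr1", "tss": 10, "tes": 5}
        with pytest.raises(ValueError):
            cis_window(ann, self.SNPS)


class TestFitCisModel:
    def test_matches_coordinate_descent_oracle(self, rng):
        X, y = _standardised_problem(rng)
        m = fit_cis_model(X, y, folds=5, seed=0)
        w_oracle, b_oracle = cd_elastic_net(X, y, m.alpha, 0.5)
        assert np.max(np.abs(m.weights - w_oracle)) <= 1e-6
        assert abs(m.intercept - b_oracle) <= 1e-6

    def test_mixing_extremes_approach_ridge_and_lasso(self, rng):
        X, y = _standardised_problem(rng)
        n = len(y)
        alpha = 0.1
        m_lasso = fit_cis_model(X, y, folds=5, mixing=1.0, seed=0)
        w_cd, _ = cd_elastic_net(X, y, m_lasso.alpha, 1.0)
        assert np.max(np.abs(m_lasso.weights - w_cd)) <= 1e-6
        # near-ridge mixing approaches the closed-form ridge solution
        from sklearn.linear_model import ElasticNet

        enet = ElasticNet(alpha=alpha, l1_ratio=0.01, max_iter=50_000, tol=1e-10)
        enet.fit(X, y)
        yc = y - y.mean()
        w_ridge = np.linalg.solve(X.T @ X / n + alpha * np.eye(X.shape[1]), X.T @ yc / n)
        assert np.max(np.abs(enet.coef_ - w_ridge)) < 0.05

    def test_null_genes_not_significant(self, rng):
        low = 0
        pvals = []
        for _ in range(30):
            X = rng.binomial(2, 0.3, size=(300, 10)).astype(float)
            y = rng.normal(size=300)
            m = fit_cis_model(X, y, folds=5, seed=1)
            low += m.cv_r2 <= 0.02
            pvals.append(m.cv_p)
        assert low >= 28
        assert not (vi.bh_fdr(pvals) < 0.05).any()

    def test_single_causal_snp_weight_recovered(self, rng):
        n = 500
        X = rng.binomial(2, 0.3, size=(n, 8)).astype(float)
        y = 1.0 * X[:, 2] + 0.1 * rng.normal(size=n)
        m = fit_cis_model(X, y, folds=10, seed=2)
        w_dosage = m.weights[2] / m.snp_sds[2]  # back to the dosage scale
        assert abs(w_dosage - 1.0) <= 0.1
        others = np.delete(np.abs(m.weights), 2)
        assert others.max() < 0.1

    def test_monomorphic_window_untrainable(self):
        X = np.ones((40, 3))
        m = fit_cis_model(X, np.random.default_rng(0).normal(size=40), folds=5)
        assert not m.trainable
        assert not m.nonzero_snps

    def test_allele_flip_leaves_predictions_unchanged(self, rng):
        X = rng.binomial(2, 0.4, size=(200, 6)).astype(float)
        y = X[:, 0] - 0.5 * X[:, 3] + 0.3 * rng.normal(size=200)
        m1 = fit_cis_model(X, y, folds=5, seed=3)
        m2 = fit_cis_model(2.0 - X, y, folds=5, seed=3)
        p1 = m1.predict(pd.DataFrame(X, columns=m1.snp_ids))
        p2 = m2.predict(pd.DataFrame(2.0 - X, columns=m2.snp_ids))
        assert np.allclose(p1, p2, atol=1e-8)
        assert np.allclose(np.abs(m1.weights), np.abs(m2.weights), atol=1e-8)


class TestTransfer:
    def test_training_data_transfer_equals_in_sample_r2(self, rng):
        X = rng.binomial(2, 0.3, size=(150, 6)).astype(float)
        y = X[:, 1] + 0.5 * rng.normal(size=150)
        m = fit_cis_model(X, y, folds=5, seed=0)
        pred = m.predict(pd.DataFrame(X, columns=m.snp_ids))
        expected = np.corrcoef(pred, y)[0, 1] ** 2
        got = evaluate_transfer(m, pd.DataFrame(X, columns=m.snp_ids), y, cohort="self")
        assert abs(got - expected) < 1e-12
        assert m.transfer_r2["self"] == got

    def test_shared_architecture_pair_retained(self):
        """h2 = 0.3 at n = (876, 344): the model transfers with R^2 >= 0.1."""
        for seed in range(3):
            cfg = vi.SimulationConfig(seed=700 + seed, n_genes=2)
            c1, c2, gt = vi.simulate_cohort_pair(cfg)
            g = "G0000"
            snps = gt.window_snps[g]
            y1 = gt.biological["cohort1"][g].to_numpy()
            m = fit_cis_model(c1.genotypes.restrict(snps), y1, gene=g, seed=seed)
            r2 = evaluate_transfer(
                m, c2.genotypes.restrict(snps), gt.biological["cohort2"][g].to_numpy(),
                cohort="cohort2",
            )
            assert m.cv_r2 >= 0.1
            assert r2 >= 0.1

    def test_shuffled_genotypes_break_transfer(self, rng):
        cfg = vi.SimulationConfig(seed=55, n_genes=2, n_individuals_per_cohort=(400, 400))
        c1, c2, gt = vi.simulate_cohort_pair(cfg)
        g = "G0000"
        snps = gt.window_snps[g]
        m = fit_cis_model(
            c1.genotypes.restrict(snps), gt.biological["cohort1"][g].to_numpy(),
            gene=g, seed=0,
        )
        dos2 = c2.genotypes.restrict(snps).dosage_frame()
        shuffled = dos2.sample(frac=1.0, random_state=1).reset_index(drop=True)
        r2 = evaluate_transfer(m, shuffled, gt.biological["cohort2"][g].to_numpy())
        assert r2 < 0.02

    def test_excess_missing_snps_flagged_non_transferable(self, rng):
        X = rng.binomial(2, 0.3, size=(200, 10)).astype(float)
        y = X[:, :4] @ np.array([1.0, 0.8, -0.9, 0.7]) + 0.2 * rng.normal(size=200)
        m = fit_cis_model(X, y, folds=5, seed=0)
        keep = [s for s in m.nonzero_snps][: max(1, int(0.6 * len(m.nonzero_snps)))]
        frame = pd.DataFrame(X, columns=m.snp_ids)[keep]
        with pytest.raises(KeyError, match="non-transferable"):
            m.predict(frame)


class TestLeadEqtl:
    def test_single_snp_window_is_lead(self, rng):
        X = rng.binomial(2, 0.3, size=(60, 1)).astype(float)
        y = X[:, 0] + rng.normal(size=60)
        le = lead_eqtl(X, y, snp_ids=["only"], n_perm=100, seed=1)
        assert le.snp_id == "only"
        assert le.perm_p < 0.05

    def test_defaults_are_thousand_permutations_with_fixed_seed(self):
        sig = inspect.signature(lead_eqtl)
        assert sig.parameters["n_perm"].default == 1000
        assert sig.parameters["seed"].default == 123456789

    def test_dosage_r2_matches_direct_regression(self, rng):
        X = rng.binomial(2, 0.4, size=(150, 5)).astype(float)
        y = 0.8 * X[:, 3] + rng.normal(size=150)
        le = lead_eqtl(X, y, n_perm=50, seed=2)
        assert le.snp_id == "snp3"
        assert abs(le.dosage_r2 - np.corrcoef(X[:, 3], y)[0, 1] ** 2) < 1e-10

    def test_zero_permutations_rejected(self, rng):
        with pytest.raises(ValueError):
            lead_eqtl(rng.binomial(2, 0.3, size=(30, 2)).astype(float),
                      rng.normal(size=30), n_perm=0)

    def test_deterministic_under_seed(self, rng):
        X = rng.binomial(2, 0.3, size=(80, 6)).astype(float)
        y = rng.normal(size=80)
        a = lead_eqtl(X, y, n_perm=200, seed=9)
        b = lead_eqtl(X, y, n_perm=200, seed=9)
        assert (a.snp_id, a.perm_p, a.statistic) == (b.snp_id, b.perm_p, b.statistic)
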