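"""Interaction scan, replication, sign concordance and co-expression."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from vset_interact.interactions import (
    ConcordanceTable,
    coexpression_table,
    coexpression_test,
    interaction_test,
    scan_and_replicate,
    scan_pairs,
    sign_concordance_chisq,
)


def _planted(rng, n=400, beta_ab=2.0, noise=0.1):
    pred = rng.normal(size=n)
    obs_b = rng.normal(size=n)
    obs_a = pred + obs_b + beta_ab * pred * obs_b + noise * rng.normal(size=n)
    return obs_a, pred, obs_b


class TestInteractionTest:
    def test_recovers_planted_coefficients_and_matches_ols_oracle(self, rng):
        obs_a, pred, obs_b = _planted(rng)
        rec = interaction_test(obs_a, pred, obs_b)
        assert 1.9 <= rec.beta_ab <= 2.1
        assert rec.p < 1e-10
        # independent oracle: normal equations
        X = np.column_stack([np.ones(len(pred)), pred, obs_b, pred * obs_b])
        beta = np.linalg.solve(X.T @ X, X.T @ obs_a)
        assert np.allclose([rec.beta_0, rec.beta_a, rec.beta_b, rec.beta_ab], beta,
                           atol=1e-8)

    def test_f_test_matches_statsmodels_and_t_squared(self, rng):
        obs_a, pred, obs_b = _planted(rng, beta_ab=0.2, noise=1.0)
        rec = interaction_test(obs_a, pred, obs_b)
        X = sm.add_constant(np.column_stack([pred, obs_b, pred * obs_b]))
        fit = sm.OLS(obs_a, X).fit()
        assert rec.p == pytest.approx(fit.pvalues[3], rel=1e-8)
        assert rec.f_stat == pytest.approx(fit.tvalues[3] ** 2, rel=1e-8)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(7)
        n, reps = 150, 1000
        hits = 0
        for _ in range(reps):
            pred = rng.normal(size=n)
            obs_b = rng.normal(size=n)
            obs_a = 0.5 * pred + 0.5 * obs_b + rng.normal(size=n)
            hits += interaction_test(obs_a, pred, obs_b).p < 0.05
        assert 0.035 <= hits / reps <= 0.065

    def test_mean_centring_invariance(self, rng):
        obs_a, pred, obs_b = _planted(rng, beta_ab=0.7, noise=0.5)
        base = interaction_test(obs_a, pred, obs_b)
        cent = interaction_test(obs_a - obs_a.mean(), pred - pred.mean(),
                                obs_b - obs_b.mean())
        assert abs(base.beta_ab - cent.beta_ab) < 1e-8
        assert base.p == pytest.approx(cent.p, rel=1e-6)

    def test_degenerate_and_collinear_inputs(self, rng):
        y = rng.normal(size=50)
        with pytest.raises(ValueError, match="constant"):
            interaction_test(y, np.ones(50), rng.normal(size=50))
        with pytest.raises(ValueError, match="differ"):
            interaction_test(y, rng.normal(size=50), rng.normal(size=50),
                             gene_a="G1", gene_b="G1")
        pred = rng.normal(size=50)
        rec = interaction_test(y, pred, pred * 1.0000001)
        assert rec.untestable and np.isnan(rec.p)


class TestScanAndReplicate:
    def _records(self, pvals, betas, cohort):
        return pd.DataFrame(
            {
                "gene_a": [f"A{i}" for i in range(len(pvals))],
                "gene_b": [f"B{i}" for i in range(len(pvals))],
                "p": pvals,
                "beta_ab": betas,
                "untestable": False,
                "cohort": cohort,
            }
        )

    def test_no_cohort1_significance_gives_empty_output(self):
        r1 = self._records([0.5, 0.8, 0.9], [1, 1, 1], "c1")
        r2 = self._records([1e-9, 1e-9, 1e-9], [1, 1, 1], "c2")
        assert len(scan_and_replicate(r1, r2)) == 0

    def test_discordant_sign_excluded_despite_significance(self):
        r1 = self._records([1e-12, 1e-12], [1.0, 1.0], "c1")
        r2 = self._records([1e-12, 1e-12], [1.0, -1.0], "c2")
        out = scan_and_replicate(r1, r2)
        assert list(out["gene_a"]) == ["A0"]

    def test_replication_fdr_computed_within_cohort1_significant_subset(self):
        # pair A0 is cohort-1 significant; its cohort-2 p of 0.03 survives an
        # FDR over 1 test but would fail an FDR over many
        p1 = [1e-12] + [0.9] * 99
        r1 = self._records(p1, [1.0] * 100, "c1")
        p2 = [0.03] + [0.5] * 99
        r2 = self._records(p2, [1.0] * 100, "c2")
        out = scan_and_replicate(r1, r2)
        assert list(out["gene_a"]) == ["A0"]

    def test_planted_pairs_recovered_among_nulls(self):
        """10 planted + 990 null pairs: the scan plus replication recovers the
        planted set with at most one false positive."""
        rng = np.random.default_rng(3)
        n1, n2 = 876, 344
        tables = {}
        for cohort, n in (("c1", n1), ("c2", n2)):
            obs, preds = {}, {}
            pairs = []
            for k in range(1000):
                pred = rng.normal(size=n)
                obs_b = rng.normal(size=n)
                beta = 0.5 if k < 10 else 0.0
                obs_a = pred + beta * pred * obs_b + rng.normal(size=n)
                obs[f"A{k}"], obs[f"B{k}"], preds[f"A{k}"] = obs_a, obs_b, pred
                pairs.append((f"A{k}", f"B{k}"))
            tables[cohort] = scan_pairs(
                pd.DataFrame(obs), pd.DataFrame(preds), pairs, cohort=cohort
            )
        out = scan_and_replicate(tables["c1"], tables["c2"])
        got = set(zip(out["gene_a"], out["gene_b"]))
        planted = {(f"A{k}", f"B{k}") for k in range(10)}
        assert len(got & planted) >= 9
        assert len(got - planted) <= 1


class TestSignConcordance:
    def test_matching_proportions_give_zero(self):
        sig = ConcordanceTable({"-/-": 10, "-/+": 20, "+/-": 30, "+/+": 40})
        ref = ConcordanceTable({"-/-": 100, "-/+": 200, "+/-": 300, "+/+": 400})
        chi2, df, p = sign_concordance_chisq(sig, ref)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 3
        assert p == pytest.approx(1.0)

    def test_hand_pearson_example(self):
        sig = ConcordanceTable({"-/-": 40, "-/+": 10, "+/-": 10, "+/+": 40})
        ref = ConcordanceTable({"-/-": 25, "-/+": 25, "+/-": 25, "+/+": 25})
        chi2, df, _ = sign_concordance_chisq(sig, ref)
        assert chi2 == pytest.approx(36.0)
        assert df == 3

    def test_empty_reference_cell_rejected(self):
        sig = ConcordanceTable({"-/-": 1, "-/+": 1, "+/-": 1, "+/+": 1})
        ref = ConcordanceTable({"-/-": 0, "-/+": 5, "+/-": 5, "+/+": 5})
        with pytest.raises(ValueError):
            sign_concordance_chisq(sig, ref)

    def test_counts_from_signs(self):
        t = ConcordanceTable.from_signs(["+", "+", "-"], ["+", "-", "-"])
        assert t.counts == {"+/+": 1, "+/-": 1, "-/-": 1, "-/+": 0}
        assert t.total == 3


class TestCoexpression:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=100)
        r, _ = coexpression_test(x, x)
        assert r == pytest.approx(1.0)

    def test_independent_profiles_near_zero(self, rng):
        r, _ = coexpression_test(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(r) < 0.08

    def test_bivariate_normal_parameter_recovery(self, rng):
        z = rng.normal(size=2000)
        x = z + 2.0 * rng.normal(size=2000)
        y = z + 2.0 * rng.normal(size=2000)  # corr = 1/5... scale to 0.2
        r, p = coexpression_test(x, y)
        assert 0.15 <= r <= 0.25
        assert p < 1e-10

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError):
            coexpression_test(np.ones(50), rng.normal(size=50))

    def test_table_summaries(self, rng):
        obs = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        t = coexpression_table(obs, [("a", "b"), ("c", "d")])
        assert set(t.columns) >= {"gene_a", "gene_b", "r", "p", "fdr"}
        assert "mean_abs_r" in t.attrs
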