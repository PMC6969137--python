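"""Generator checks: Hardy–Weinberg moments, determinism, planted effects."""

import numpy as np
import pandas as pd
import pytest

import vset_interact as vi
from vset_interact.simulate import SimulationConfig
from vset_interact.veqtl import veqtl_test

COORDS = pd.DataFrame({"chrom": ["chr1"] * 20, "pos": np.arange(100, 2100, 100)})


class TestSimulateGenotypes:
    def test_symmetric_allele_mean_dosage(self):
        g = vi.simulate_genotypes(10_000, COORDS, (0.5, 0.5), seed=1)
        assert np.allclose(g.dosages.mean(axis=0), 1.0, atol=0.02)

    def test_hwe_variance_matches_closed_form(self):
        # Var(dosage) = 2 p (1 - p) = 0.32 at p = 0.2
        g = vi.simulate_genotypes(100_000, COORDS, (0.2, 0.2), seed=2)
        assert np.allclose(g.dosages.var(axis=0), 0.32, atol=0.01)

    def test_same_seed_identical(self):
        a = vi.simulate_genotypes(50, COORDS, (0.1, 0.4), seed=7)
        b = vi.simulate_genotypes(50, COORDS, (0.1, 0.4), seed=7)
        assert np.array_equal(a.dosages, b.dosages)
        assert list(a.snps["maf"]) == list(b.snps["maf"])

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n=1),
            dict(maf_range=(0.0, 0.4)),
            dict(maf_range=(0.2, 1.0)),
            dict(coords=pd.DataFrame({"chrom": [], "pos": []})),
            dict(coords=pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [5, 5]})),
        ],
    )
    def test_invalid_inputs_rejected(self, kwargs):
        n = kwargs.get("n", 10)
        coords = kwargs.get("coords", COORDS)
        maf = kwargs.get("maf_range", (0.1, 0.4))
        with pytest.raises(ValueError):
            vi.simulate_genotypes(n, coords, maf, seed=0)


class TestConfigValidation:
    def test_interaction_on_gene_without_cis_signal_rejected(self):
        cfg = SimulationConfig(cis_heritability=0.0, interaction_pairs=[(0, 1, 0.5)])
        with pytest.raises(ValueError, match="unidentifiable"):
            cfg.validate()

    def test_pair_index_out_of_range_rejected(self):
        cfg = SimulationConfig(n_genes=5, interaction_pairs=[(0, 7, 0.5)])
        with pytest.raises(ValueError):
            cfg.validate()

    def test_target_partner_overlap_rejected(self):
        cfg = SimulationConfig(interaction_pairs=[(0, 1, 0.5), (1, 2, 0.5)])
        with pytest.raises(ValueError, match="acyclic"):
            cfg.validate()

    @pytest.mark.parametrize("field,value", [
        ("n_individuals_per_cohort", (1, 100)),
        ("maf_range", (0.0, 0.5)),
        ("cis_heritability", 1.0),
        ("heavy_tail_fraction", 1.5),
    ])
    def test_invalid_fields_rejected(self, field, value):
        cfg = SimulationConfig(**{field: value})
        with pytest.raises(ValueError):
            cfg.validate()


class TestCohortPair:
    def test_fixed_seed_byte_identical(self):
        cfg = vi.default_config(seed=5, n_individuals_per_cohort=(40, 30), n_genes=6,
                                interaction_pairs=[(0, 1, 0.5)])
        a1, a2, _ = vi.simulate_cohort_pair(cfg)
        b1, b2, _ = vi.simulate_cohort_pair(cfg)
        assert a1.expression.equals(b1.expression)
        assert a2.expression.equals(b2.expression)
        assert np.array_equal(a1.genotypes.dosages, b1.genotypes.dosages)
        assert a1.covariates.equals(b1.covariates)

    def test_shared_architecture_differs_only_in_draws(self, small_pair):
        c1, c2, gt = small_pair
        assert list(c1.genotypes.snps.index) == list(c2.genotypes.snps.index)
        assert np.allclose(c1.genotypes.snps["maf"], c2.genotypes.snps["maf"])
        assert not np.array_equal(
            c1.genotypes.dosages[: c2.n_individuals], c2.genotypes.dosages
        )

    def test_null_generator_veqtl_calibration(self):
        """Without planted interactions the variance screen rejects ~5%."""
        hits = 0
        total = 0
        for seed in range(5):
            cfg = SimulationConfig(
                seed=100 + seed, n_individuals_per_cohort=(500, 50), n_genes=40,
            )
            _, _, gt = vi.simulate_cohort_pair(cfg)
            scores = gt.genetic_scores["cohort1"]
            bio = gt.biological["cohort1"]
            for g in scores.columns:
                total += 1
                hits += veqtl_test(scores[g].to_numpy(), bio[g].to_numpy()).p < 0.05
        assert 0.02 <= hits / total <= 0.09

    def test_conditional_variance_matches_closed_form(self):
        """Planted beta_ab = 0.5: residual variance in the top quartile of the
        true genetic score exceeds the bottom quartile, by the amount the
        generative model predicts (sigma_e^2 + (beta_ab * g)^2 * var_B)."""
        gaps = []
        for seed in range(3):
            cfg = SimulationConfig(
                seed=1500 + seed, n_individuals_per_cohort=(2000, 100), n_genes=4,
                n_causal_cis=2, maf_range=(0.05, 0.2),
                interaction_pairs=[(0, 1, 0.5)],
            )
            _, _, gt = vi.simulate_cohort_pair(cfg)
            s = gt.genetic_scores["cohort1"]["G0000"].to_numpy()
            y = gt.biological["cohort1"]["G0000"].to_numpy()
            resid = y - np.polyval(np.polyfit(s, y, 1), s)
            qlo, qhi = np.quantile(s, [0.25, 0.75])
            lo, hi = s <= qlo, s >= qhi
            emp = resid[hi].var() - resid[lo].var()
            # var_B = h2 + noise_sd^2 = 1 in cohort 1 under these conditions
            analytic = 0.25 * ((s[hi] ** 2).mean() - (s[lo] ** 2).mean())
            assert emp > 0
            assert abs(emp - analytic) < 0.2  # ~2.5 sigma of the quartile estimator
            gaps.append(abs(emp - analytic))
        assert np.mean(gaps) < 0.1

    def test_pure_interaction_pairs_barely_coexpressed(self):
        """With beta_b = 0 the planted pairs show near-zero marginal correlation."""
        cfg = vi.default_config(seed=11, n_individuals_per_cohort=(2000, 100))
        _, _, gt = vi.simulate_cohort_pair(cfg)
        bio = gt.biological["cohort1"]
        rs = [
            abs(np.corrcoef(bio[p["gene_a"]], bio[p["gene_b"]])[0, 1])
            for p in gt.interaction_pairs
        ]
        assert np.mean(rs) < 0.05
        assert max(rs) < 0.1

    def test_absolute_residual_slope_positive_iff_interaction(self):
        """Fig-3-style pattern: |residual| grows along the genetic score only
        for genes with a planted interaction."""
        cfg = vi.veqtl_demo_config(seed=21, n_individuals_per_cohort=(2000, 100))
        _, _, gt = vi.simulate_cohort_pair(cfg)
        bio, scores = gt.biological["cohort1"], gt.genetic_scores["cohort1"]

        def slope_t(gene):
            s = scores[gene].to_numpy()
            y = bio[gene].to_numpy()
            resid = np.abs(y - np.polyval(np.polyfit(s, y, 1), s))
            X = np.column_stack([np.ones_like(s), s])
            beta, *_ = np.linalg.lstsq(X, resid, rcond=None)
            se = np.sqrt(
                np.sum((resid - X @ beta) ** 2) / (len(s) - 2)
                / np.sum((s - s.mean()) ** 2)
            )
            return beta[1] / se

        assert slope_t("G0000") > 3  # planted interaction target
        assert abs(slope_t("G0002")) < 3  # no interaction

    def test_transfer_r2_approaches_cis_heritability(self):
        """With unit-variance genes, corr^2(true score, expression) ~ h2."""
        cfg = SimulationConfig(seed=31, n_individuals_per_cohort=(2000, 2000), n_genes=8)
        _, _, gt = vi.simulate_cohort_pair(cfg)
        for cohort, noise_sd in zip(("cohort1", "cohort2"), cfg.noise_sd):
            r2 = []
            for g in gt.gene_names():
                s = gt.genetic_scores[cohort][g].to_numpy()
                y = gt.biological[cohort][g].to_numpy()
                r2.append(np.corrcoef(s, y)[0, 1] ** 2)
            expected = cfg.cis_heritability / (cfg.cis_heritability + noise_sd**2)
            assert abs(np.mean(r2) - expected) < 0.03

    def test_heavy_tail_genes_fail_kurtosis_filter(self):
        cfg = SimulationConfig(seed=41, n_individuals_per_cohort=(2000, 100),
                               n_genes=20, heavy_tail_fraction=0.25)
        _, _, gt = vi.simulate_cohort_pair(cfg)
        heavy = [g for g, fam in gt.noise_family.items() if fam == "student_t3"]
        assert len(heavy) == 5
        part = vi.kurtosis_filter(gt.biological["cohort1"], threshold=9.0)
        flagged = set(part.excluded)
        # heavy-tailed genes should dominate the exclusions
        assert len(flagged & set(heavy)) >= 3
        assert len(flagged - set(heavy)) <= 1
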