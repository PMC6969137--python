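"""Paired synthetic cohorts with known cis architecture and planted interactions.

The generator produces two cohorts of unequal size that share the same true
cis-regulatory weights (the biology) while differing in sample size and
measurement noise (the platforms).  Each gene's expression is

``obs = sqrt(h2) * s + [beta_b * b_B + beta_ab * sqrt(h2) * s * b_B] + covariates + batch + noise``

where ``s`` is the gene's genetic score — the weighted sum of its causal
cis dosages, centred and scaled to unit variance using the Hardy–Weinberg
moments of the shared allele frequencies so the same standardisation
applies in both cohorts — and ``b_B`` is the pre-nuisance (biological)
expression of the distal partner gene.  Because causal weights are positive
and minor alleles are the rarer ones, ``s`` is right-skewed: individuals
carrying unusually many expression-increasing alleles form a long upper
tail.  A planted interaction therefore produces the classic
variance-heterogeneity signature — residual spread that grows along the
predicted-expression axis — while the marginal correlation between the two
genes stays near zero when ``beta_b = 0`` (the score is centred, so the
interaction term is uncorrelated with ``b_B``).

Nuisance structure: fixed covariate effects (age, sex, five ancestry PCs),
random plate/array intercepts, and per-cohort noise.  Cohort 1 noise is
Gaussian and homoskedastic ("microarray-like"); cohort 2 can add a
mean–variance coupling ("RNA-seq-like", ``rnaseq_coupling``).  A configurable
fraction of non-interacting genes receives Student-t (df=3) noise to
exercise the kurtosis filter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CohortData, GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_genotypes",
    "simulate_cohort_pair",
    "default_config",
    "veqtl_demo_config",
    "write_cohort",
]

_T3_SD = np.sqrt(3.0)  # Student-t(3) standard deviation


@dataclass
class SimulationConfig:
    """Study conditions for a paired-cohort simulation.

    Defaults mirror the two-cohort design the pipeline targets: 876 and 344
    individuals, sparse cis effects inside +/-1 Mb windows, cis heritability
    0.3, and residual noise scaled so a non-interacting gene has roughly
    unit variance (the second cohort is noisier, as an RNA-seq replication
    panel measured on a different platform would be).
    """

    n_individuals_per_cohort: tuple[int, int] = (876, 344)
    n_genes: int = 30
    n_snps_per_window: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    cis_heritability: float = 0.3
    n_causal_cis: int = 5
    interaction_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    main_effect_beta_b: float = 0.0
    noise_sd: tuple[float, float] = (0.84, 1.0)
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.02, "sex": 0.2, "pc": 0.1}
    )
    batch_sd: float = 0.3
    heavy_tail_fraction: float = 0.0
    rnaseq_coupling: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        n1, n2 = self.n_individuals_per_cohort
        if n1 < 2 or n2 < 2:
            raise ValueError("cohort sizes must be >= 2")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"maf_range must lie within (0, 1), got {self.maf_range}")
        if not (0.0 <= self.cis_heritability < 1.0):
            raise ValueError("cis_heritability must be in [0, 1)")
        if self.n_genes < 1 or self.n_snps_per_window < 1:
            raise ValueError("n_genes and n_snps_per_window must be positive")
        if not (0.0 <= self.heavy_tail_fraction <= 1.0):
            raise ValueError("heavy_tail_fraction must be in [0, 1]")
        targets = set()
        sources = set()
        for ia, ib, beta in self.interaction_pairs:
            if not (0 <= ia < self.n_genes and 0 <= ib < self.n_genes):
                raise ValueError(f"interaction pair ({ia}, {ib}) references a gene >= n_genes")
            if ia == ib:
                raise ValueError("interaction pair cannot pair a gene with itself")
            if self.cis_heritability == 0.0 or self.n_causal_cis == 0:
                raise ValueError(
                    "interaction planted on a gene with zero cis heritability: "
                    "its variant-set is unidentifiable"
                )
            targets.add(ia)
            sources.add(ib)
        overlap = targets & sources
        if overlap:
            raise ValueError(
                f"genes {sorted(overlap)} appear as both interaction target and partner; "
                "the generative model requires an acyclic target/partner split"
            )


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream recovery checks."""

    config: SimulationConfig
    window_snps: dict[str, list[str]]
    cis_weights: dict[str, np.ndarray]  # per gene, full-window dosage-scale weights
    score_mean: dict[str, float]
    score_sd: dict[str, float]
    interaction_pairs: list[dict]
    covariate_effects: dict[str, float]
    noise_family: dict[str, str]
    genetic_scores: dict[str, pd.DataFrame]  # cohort -> individuals x genes (sqrt(h2)*s)
    biological: dict[str, pd.DataFrame]  # cohort -> pre-nuisance expression

    def gene_names(self) -> list[str]:
        return list(self.window_snps)


def _as_coord_frame(snp_coords) -> pd.DataFrame:
    if isinstance(snp_coords, pd.DataFrame):
        coords = snp_coords[["chrom", "pos"]].copy()
    else:
        coords = pd.DataFrame(list(snp_coords), columns=["chrom", "pos"])
    if len(coords) == 0:
        raise ValueError("empty SNP coordinate list")
    for chrom, grp in coords.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"SNP positions on {chrom} must be strictly increasing")
    return coords


def _draw_dosages(rng: np.random.Generator, n: int, mafs: np.ndarray) -> np.ndarray:
    """Hard-call dosages under Hardy–Weinberg equilibrium, one MAF per SNP."""
    return rng.binomial(2, mafs[None, :], size=(n, len(mafs))).astype(float)


def simulate_genotypes(n: int, snp_coords, maf_range, seed: int) -> GenotypeMatrix:
    """Simulate unlinked Hardy–Weinberg dosages at the given coordinates.

    Parameters
    ----------
    n
        Number of individuals (>= 2).
    snp_coords
        DataFrame with ``chrom``/``pos`` columns or an iterable of
        ``(chrom, pos)`` pairs; positions must be strictly increasing per
        chromosome.
    maf_range
        ``(low, high)`` bounds in (0, 1); each SNP's minor-allele frequency
        is drawn uniformly from this interval.
    seed
        Seed for the generator; a fixed seed reproduces the matrix exactly.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    lo, hi = maf_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError(f"maf_range must lie within (0, 1), got {maf_range}")
    coords = _as_coord_frame(snp_coords)
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=len(coords))
    dosages = _draw_dosages(rng, n, mafs)
    snps = coords.copy()
    snps["ref"] = "A"
    snps["alt"] = "B"
    snps["maf"] = mafs
    snps.index = [f"snp_{c}_{p}" for c, p in zip(coords["chrom"], coords["pos"])]
    individuals = [f"ind_{i:05d}" for i in range(n)]
    return GenotypeMatrix(dosages=dosages, snps=snps, individuals=individuals)


def _gene_layout(n_genes: int) -> pd.DataFrame:
    """Place genes 10 Mb apart, ten per chromosome, so cis windows never overlap."""
    rows = []
    for i in range(n_genes):
        chrom = f"chr{i // 10 + 1}"
        tss = 4_000_000 + (i % 10) * 10_000_000
        rows.append(
            {
                "probe": f"G{i:04d}",
                "gene": f"G{i:04d}",
                "chrom": chrom,
                "tss": tss,
                "tes": tss + 50_000,
                "strand": "+",
            }
        )
    return pd.DataFrame(rows)


def simulate_cohort_pair(config: SimulationConfig) -> tuple[CohortData, CohortData, GroundTruth]:
    """Generate two cohorts sharing cis architecture, plus the ground truth.

    Both cohorts use the same causal weights, allele frequencies and gene
    layout; genotypes, covariates and noise are drawn independently per
    cohort.  Interaction-partner genes (gene B) are generated before their
    targets (gene A) so the planted term ``beta_ab * genetic_A * b_B`` uses
    gene B's biological (pre-nuisance) expression.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_shared, ss_c1, ss_c2 = root.spawn(3)
    rng_shared = np.random.default_rng(ss_shared)

    annotation = _gene_layout(config.n_genes)
    genes = list(annotation["gene"])
    lo, hi = config.maf_range
    h2 = config.cis_heritability
    n_caus = min(config.n_causal_cis, config.n_snps_per_window)

    # shared architecture: window SNPs, allele frequencies, positive causal weights
    snp_rows = []
    window_snps: dict[str, list[str]] = {}
    mafs_all = []
    weights: dict[str, np.ndarray] = {}
    score_mean: dict[str, float] = {}
    score_sd: dict[str, float] = {}
    for _, g in annotation.iterrows():
        start = max(1, int(g.tss) - 1_000_000)
        end = int(g.tes) + 1_000_000
        pos = np.sort(
            rng_shared.choice(np.arange(start, end + 1), size=config.n_snps_per_window, replace=False)
        )
        ids = [f"snp_{g.chrom}_{p}" for p in pos]
        window_snps[g.gene] = ids
        gene_mafs = rng_shared.uniform(lo, hi, size=config.n_snps_per_window)
        mafs_all.append(gene_mafs)
        for i, p in zip(ids, pos):
            snp_rows.append({"id": i, "chrom": g.chrom, "pos": int(p)})
        w = np.zeros(config.n_snps_per_window)
        if h2 > 0 and n_caus > 0:
            causal = rng_shared.choice(config.n_snps_per_window, size=n_caus, replace=False)
            w[causal] = np.abs(rng_shared.normal(0.0, 1.0, size=n_caus)) + 0.1
        weights[g.gene] = w
        var = float(np.sum(w**2 * 2 * gene_mafs * (1 - gene_mafs)))
        score_sd[g.gene] = np.sqrt(var) if var > 0 else 1.0
        score_mean[g.gene] = float(np.sum(w * 2 * gene_mafs))

    snp_table = pd.DataFrame(snp_rows).set_index("id")
    snp_table["ref"] = "A"
    snp_table["alt"] = "B"
    snp_table["maf"] = np.concatenate(mafs_all)

    # noise family: heavy-tailed genes drawn from genes not in any pair
    in_pairs = {genes[ia] for ia, _, _ in config.interaction_pairs} | {
        genes[ib] for _, ib, _ in config.interaction_pairs
    }
    eligible = [g for g in genes if g not in in_pairs]
    n_heavy = int(round(config.heavy_tail_fraction * config.n_genes))
    heavy = set(
        rng_shared.choice(eligible, size=min(n_heavy, len(eligible)), replace=False)
        if eligible and n_heavy
        else []
    )
    noise_family = {g: ("student_t3" if g in heavy else "gaussian") for g in genes}

    pairs_by_target: dict[int, list[tuple[int, float]]] = {}
    for ia, ib, beta in config.interaction_pairs:
        pairs_by_target.setdefault(ia, []).append((ib, beta))
    order = [i for i in range(config.n_genes) if i not in pairs_by_target] + list(pairs_by_target)

    cohorts = []
    gt_scores: dict[str, pd.DataFrame] = {}
    gt_bio: dict[str, pd.DataFrame] = {}
    for c, (n, ss, noise_sd) in enumerate(
        zip(config.n_individuals_per_cohort, (ss_c1, ss_c2), config.noise_sd)
    ):
        rng = np.random.default_rng(ss)
        name = f"cohort{c + 1}"
        individuals = [f"{name}_ind{i:05d}" for i in range(n)]
        dosages = _draw_dosages(rng, n, snp_table["maf"].to_numpy())
        geno = GenotypeMatrix(dosages=dosages, snps=snp_table.copy(), individuals=individuals)
        dos = geno.dosage_frame()

        scores = np.empty((n, config.n_genes))
        for j, g in enumerate(genes):
            raw = dos[window_snps[g]].to_numpy() @ weights[g]
            scores[:, j] = (raw - score_mean[g]) / score_sd[g]
        genetic = np.sqrt(h2) * scores  # variance h2 per gene

        coupling = config.rnaseq_coupling if c == 1 else 0.0
        bio = np.empty((n, config.n_genes))
        for j in order:
            g = genes[j]
            mu = genetic[:, j].copy()
            for ib, beta_ab in pairs_by_target.get(j, []):
                mu += config.main_effect_beta_b * bio[:, ib] + beta_ab * genetic[:, j] * bio[:, ib]
            sd = noise_sd * np.sqrt(1.0 + coupling * np.abs(mu))
            if noise_family[g] == "student_t3":
                eps = rng.standard_t(3, size=n) / _T3_SD * sd
            else:
                eps = rng.normal(0.0, 1.0, size=n) * sd
            bio[:, j] = mu + eps

        # nuisance: covariates and batch intercepts added to every gene
        eff = config.covariate_effects
        age = rng.normal(70.0, 4.0, size=n)
        sex = rng.integers(0, 2, size=n).astype(float)
        pcs = rng.normal(0.0, 1.0, size=(n, 5))
        plate = np.array([f"plate{i // 24:03d}" for i in range(n)])
        array = np.array([f"array{i // 8:04d}" for i in range(n)])
        plate_eff = {
            p: rng.normal(0.0, config.batch_sd) for p in pd.unique(plate)
        }
        array_eff = {
            a: rng.normal(0.0, config.batch_sd / 2.0) for a in pd.unique(array)
        }
        nuisance = (
            eff.get("age", 0.0) * (age - 70.0)
            + eff.get("sex", 0.0) * sex
            + eff.get("pc", 0.0) * pcs.sum(axis=1)
            + np.array([plate_eff[p] for p in plate])
            + np.array([array_eff[a] for a in array])
        )
        expr = pd.DataFrame(
            bio + nuisance[:, None], index=individuals, columns=genes
        )
        covariates = pd.DataFrame(
            {
                "age": age,
                "sex": sex,
                **{f"PC{k + 1}": pcs[:, k] for k in range(5)},
                "plate": plate,
                "array": array,
            },
            index=individuals,
        )
        cohorts.append(
            CohortData(
                name=name,
                genotypes=geno,
                expression=expr,
                annotation=annotation.copy(),
                covariates=covariates,
            )
        )
        gt_scores[name] = pd.DataFrame(genetic, index=individuals, columns=genes)
        gt_bio[name] = pd.DataFrame(bio, index=individuals, columns=genes)

    truth = GroundTruth(
        config=config,
        window_snps=window_snps,
        cis_weights=weights,
        score_mean=score_mean,
        score_sd=score_sd,
        interaction_pairs=[
            {
                "gene_a": genes[ia],
                "gene_b": genes[ib],
                "beta_ab": beta,
                "beta_b": config.main_effect_beta_b,
            }
            for ia, ib, beta in config.interaction_pairs
        ],
        covariate_effects=dict(config.covariate_effects),
        noise_family=noise_family,
        genetic_scores=gt_scores,
        biological=gt_bio,
    )
    return cohorts[0], cohorts[1], truth


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Paired-cohort study conditions with ten planted pure interactions.

    Pure interactions (``beta_b = 0``) with effect size 0.5 on genes spread
    across chromosomes; partners are distinct non-target genes.  These are
    the conditions used for scan/replication recovery checks.
    """
    pairs = [(2 * k, 2 * k + 1, 0.5) for k in range(10)]
    fields = {"seed": seed, "interaction_pairs": pairs}
    fields.update(overrides)
    n_genes = fields.get("n_genes", SimulationConfig.n_genes)
    fields["interaction_pairs"] = [
        (a, b, beta) for a, b, beta in fields["interaction_pairs"] if a < n_genes and b < n_genes
    ]
    cfg = SimulationConfig(**fields)
    cfg.validate()
    return cfg


def veqtl_demo_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Conditions for illustrating variant-set-dependent variance.

    A strong interaction (``beta_ab = 1.2``) combined with a same-sign main
    effect (``beta_b = 0.6``) on a gene whose cis score is dominated by two
    low-frequency causal variants.  The main effect places the vertex of
    the conditional-variance parabola ``(beta_b + beta_ab*g)^2`` below the
    observed score range, so residual spread grows monotonically along the
    score — the regime in which expression is high only under the right
    combination of variant-set and partner-gene level, and in which
    variance-heterogeneity screens have power.  The right skew of the
    low-frequency score adds to the monotonicity.
    """
    base = dict(
        n_genes=10,
        n_causal_cis=2,
        maf_range=(0.05, 0.25),
        interaction_pairs=[(0, 1, 1.2)],
        main_effect_beta_b=0.6,
        seed=seed,
    )
    base.update(overrides)
    cfg = SimulationConfig(**base)
    cfg.validate()
    return cfg


def write_cohort(cohort: CohortData, outdir) -> None:
    """Write a cohort to ``outdir`` as plain-text tables.

    Genotypes go to a PLINK-style dosage text file (SNP id, alleles, one
    dosage per individual), expression/covariates/annotation to TSV.
    """
    from . import io as vio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    vio.write_dosage(cohort.genotypes, out / "genotypes.dosage.txt")
    vio.write_expression(cohort.expression, out / "expression.tsv")
    vio.write_table(cohort.annotation, out / "annotation.tsv")
    vio.write_table(cohort.covariates.reset_index(names="individual"), out / "covariates.tsv")


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Serialise planted parameters (not per-individual scores) as JSON."""
    payload = {
        "interaction_pairs": truth.interaction_pairs,
        "covariate_effects": truth.covariate_effects,
        "noise_family": truth.noise_family,
        "cis_weights": {
            g: {s: float(w) for s, w in zip(truth.window_snps[g], truth.cis_weights[g]) if w != 0.0}
            for g in truth.window_snps
        },
        "score_mean": truth.score_mean,
        "score_sd": truth.score_sd,
        "seed": truth.config.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
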