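"""End-to-end orchestration: preprocess -> cis models -> veQTL -> scan ->
confounders -> variance -> enrichment.

:func:`run_pipeline` consumes two :class:`~vset_interact.data.CohortData`
objects (cohort 1 is the training cohort, cohort 2 the replication cohort)
and returns a :class:`PipelineResult` bundle of tables.  All randomness is
drawn from named substreams of a single master seed, so every stage is
individually reproducible and a fixed-seed run writes byte-identical
output.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as vio
from .cis import CisModel, cis_window, evaluate_transfer, fit_cis_model, retain_genes
from .confounders import (
    geneB_eqtl_adjusted_test,
    genetic_interaction_test,
    snp_confounder_test,
    third_gene_test,
)
from .data import CohortData
from .enrichment import hypergeometric_enrichment
from .interactions import (
    ConcordanceTable,
    coexpression_table,
    scan_and_replicate,
    scan_pairs,
    sign_concordance_chisq,
)
from .preprocess import kurtosis_filter, regress_covariates, remove_hidden_factors
from .variance import prune_correlated, pseudo_r2_decomposition, stepwise_variance
from .veqtl import veqtl_scan

log = logging.getLogger("vset_interact")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_results"]


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage substream seed below 2**31."""
    return (int(master) * 2654435761 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Thresholds, seeds and stage toggles for a full run."""

    transfer_r2_threshold: float = 0.1
    kurtosis_threshold: float = 9.0
    fdr: float = 0.05
    correlation_cutoff: float = 0.4
    k_max_hidden: int = 10
    cv_folds: int = 10
    elastic_net_mixing: float = 0.5
    cis_exclusion_bp: int = 1_000_000
    n_random_third_genes: int = 1000
    stepwise_iterations: int = 100
    train_frac: float = 0.8
    seed: int = 0
    run_confounders: bool = True
    run_variance: bool = True

    def validate(self) -> None:
        if not (0.0 <= self.transfer_r2_threshold <= 1.0):
            raise ValueError("transfer_r2_threshold must be in [0, 1]")
        if self.kurtosis_threshold <= 0:
            raise ValueError("kurtosis_threshold must be positive")
        if not (0.0 < self.fdr < 1.0):
            raise ValueError("fdr must be in (0, 1)")
        if not (0.0 < self.correlation_cutoff <= 1.0):
            raise ValueError("correlation_cutoff must be in (0, 1]")
        if not (0.0 < self.train_frac < 1.0):
            raise ValueError("train_frac must be in (0, 1)")


@dataclass
class PipelineResult:
    retention: pd.DataFrame
    retained_genes: list[str]
    veqtl: dict[str, pd.DataFrame]
    veqtl_replicated: list[str]
    scans: dict[str, pd.DataFrame]
    replicated: pd.DataFrame
    concordance: dict
    coexpression: pd.DataFrame
    verdicts: pd.DataFrame
    putative: pd.DataFrame
    variance: pd.DataFrame
    stepwise: pd.DataFrame
    enrichment: pd.DataFrame | None
    funnel: dict[str, int]
    models: dict[str, CisModel] = field(default_factory=dict)


def _align_probes(c1: CohortData, c2: CohortData) -> list[str]:
    shared = [p for p in c1.expression.columns if p in set(c2.expression.columns)]
    if not shared:
        raise ValueError("cohorts share no probes")
    return shared


def run_pipeline(
    cohort1: CohortData,
    cohort2: CohortData,
    config: PipelineConfig | None = None,
    gene_sets: dict[str, set] | None = None,
) -> PipelineResult:
    """Run every stage on a cohort pair and return the result bundle."""
    cfg = config or PipelineConfig()
    cfg.validate()
    funnel: dict[str, int] = {}
    probes = _align_probes(cohort1, cohort2)
    funnel["probes_shared"] = len(probes)

    # --- preprocess -------------------------------------------------------
    resid: dict[str, pd.DataFrame] = {}
    kurt_pass: dict[str, set] = {}
    for c in (cohort1, cohort2):
        r = regress_covariates(c.expression[probes], c.covariates)
        k_max = min(cfg.k_max_hidden, c.n_individuals - 1, len(probes) - 1)
        r = remove_hidden_factors(
            r, k_max=k_max, seed=stage_seed(cfg.seed, f"hidden:{c.name}")
        )
        resid[c.name] = r.values
        part = kurtosis_filter(r.values, threshold=cfg.kurtosis_threshold)
        kurt_pass[c.name] = set(part.retained)
        log.info("%s: %d hidden factors removed, %d/%d probes pass kurtosis",
                 c.name, r.n_hidden_factors, len(part.retained), len(probes))
    kurt_both = [p for p in probes if p in kurt_pass[cohort1.name] and p in kurt_pass[cohort2.name]]
    funnel["probes_kurtosis_pass"] = len(kurt_both)

    # --- cis models (trained on cohort 1, transferred to cohort 2) -------
    ann = cohort1.annotation.set_index("probe")
    models: dict[str, CisModel] = {}
    preds: dict[str, dict[str, np.ndarray]] = {cohort1.name: {}, cohort2.name: {}}
    r2s: dict[str, dict[str, float]] = {cohort1.name: {}, cohort2.name: {}}
    for g in kurt_both:
        win = cis_window(ann.loc[g], cohort1.genotypes.snps)
        if not win.snp_ids:
            continue
        G1 = cohort1.genotypes.restrict(win.snp_ids)
        y1 = resid[cohort1.name][g].to_numpy()
        m = fit_cis_model(
            G1, y1, gene=g, folds=cfg.cv_folds, mixing=cfg.elastic_net_mixing,
            seed=stage_seed(cfg.seed, f"cis:{g}"),
        )
        models[g] = m
        if not m.trainable:
            continue
        preds[cohort1.name][g] = m.predict(G1)
        r2s[cohort1.name][g] = m.cv_r2
        try:
            r2 = evaluate_transfer(
                m, cohort2.genotypes.restrict(win.snp_ids),
                resid[cohort2.name][g].to_numpy(), cohort=cohort2.name,
            )
            preds[cohort2.name][g] = m.predict(cohort2.genotypes.restrict(win.snp_ids))
            r2s[cohort2.name][g] = r2
        except KeyError:
            r2s[cohort2.name][g] = 0.0
    funnel["models_trained"] = sum(m.trainable for m in models.values())

    pred_frames = {
        name: pd.DataFrame(cols, index=resid[name].index)
        for name, cols in preds.items()
    }
    retained, retention = retain_genes(
        models, pred_frames, r2s,
        r2_threshold=cfg.transfer_r2_threshold,
        kurtosis_threshold=cfg.kurtosis_threshold,
        fdr_threshold=cfg.fdr,
    )
    retained_genes = sorted(retained)
    funnel["genes_retained"] = len(retained_genes)
    log.info("retained %d genes with reproducible cis models", len(retained_genes))

    # --- veQTL ------------------------------------------------------------
    veqtl_tables: dict[str, pd.DataFrame] = {}
    sig_sets = []
    for name in (cohort1.name, cohort2.name):
        tab = veqtl_scan(pred_frames[name], resid[name], genes=retained_genes)
        tab["cohort"] = name
        veqtl_tables[name] = tab
        sig_sets.append(set(tab.loc[tab["fdr"] < cfg.fdr, "gene"]))
    veqtl_replicated = sorted(sig_sets[0] & sig_sets[1]) if sig_sets else []
    funnel["veqtl_replicated"] = len(veqtl_replicated)

    # --- interaction scan -------------------------------------------------
    pairs: list[tuple[str, str]] = []
    for a in retained_genes:
        a_chrom = ann.loc[a, "chrom"]
        a_lo = max(1, int(ann.loc[a, "tss"]) - cfg.cis_exclusion_bp)
        a_hi = int(ann.loc[a, "tes"]) + cfg.cis_exclusion_bp
        a_gene = ann.loc[a, "gene"]
        for b in kurt_both:
            if b == a or ann.loc[b, "gene"] == a_gene:
                continue
            if ann.loc[b, "chrom"] == a_chrom and not (
                int(ann.loc[b, "tes"]) < a_lo or int(ann.loc[b, "tss"]) > a_hi
            ):
                continue  # cis-contaminated pair
            pairs.append((a, b))
    funnel["pairs_tested"] = len(pairs)

    scans = {
        name: scan_pairs(resid[name], pred_frames[name], pairs, cohort=name)
        for name in (cohort1.name, cohort2.name)
    }
    replicated = scan_and_replicate(scans[cohort1.name], scans[cohort2.name], fdr=cfg.fdr)
    funnel["pairs_replicated"] = len(replicated)

    # sign concordance: significant-in-both pairs (before the sign filter)
    # against all pairs tested in both cohorts
    merged = scans[cohort1.name].merge(
        scans[cohort2.name], on=["gene_a", "gene_b"], suffixes=("_1", "_2")
    )
    merged = merged[~(merged["untestable_1"] | merged["untestable_2"])]
    concordance: dict = {"chi2": np.nan, "df": 3, "p": np.nan}
    if len(merged):
        all_tab = ConcordanceTable.from_signs(merged["sign_1"], merged["sign_2"])
        sig_mask = (merged["fdr_1"] < cfg.fdr) & (merged["fdr_2"] < cfg.fdr)
        sig_tab = ConcordanceTable.from_signs(
            merged.loc[sig_mask, "sign_1"], merged.loc[sig_mask, "sign_2"]
        )
        concordance["significant_counts"] = sig_tab.counts
        concordance["all_counts"] = all_tab.counts
        if all(v > 0 for v in all_tab.counts.values()) and sig_tab.total > 0:
            chi2, df, p = sign_concordance_chisq(sig_tab, all_tab)
            concordance.update({"chi2": chi2, "df": df, "p": p})

    rep_pairs = list(zip(replicated["gene_a"], replicated["gene_b"])) if len(replicated) else []
    coexpr = coexpression_table(resid[cohort1.name], rep_pairs)

    # --- confounders ------------------------------------------------------
    verdict_rows = []
    snp_flagged: set[tuple[str, str]] = set()
    third_flagged: set[tuple[str, str]] = set()
    if cfg.run_confounders and rep_pairs:
        rng = np.random.default_rng(stage_seed(cfg.seed, "third_gene"))
        partners_of: dict[str, set] = {}
        for a, b in rep_pairs:
            partners_of.setdefault(a, set()).add(b)
        for a, b in rep_pairs:
            for c in (cohort1, cohort2):
                name = c.name
                obs_a = resid[name][a].to_numpy()
                pred_a = pred_frames[name][a].to_numpy()
                obs_b = resid[name][b].to_numpy()
                win = cis_window(ann.loc[a], c.genotypes.snps)
                wd = c.genotypes.restrict(win.snp_ids).dosage_frame()
                v_snp = snp_confounder_test(obs_a, pred_a, obs_b, wd, gene_a=a, gene_b=b)

                network = sorted(partners_of[a] - {b})
                pool = [p for p in kurt_both if p not in {a, b} and p not in network]
                n_extra = min(cfg.n_random_third_genes, len(pool))
                extra = sorted(rng.choice(pool, size=n_extra, replace=False)) if n_extra else []
                cand = resid[name][network + list(extra)]
                v_third = third_gene_test(obs_a, pred_a, obs_b, cand, gene_a=a, gene_b=b)

                if b in pred_frames[name].columns:
                    pred_b = pred_frames[name][b].to_numpy()
                    v_gen = genetic_interaction_test(obs_a, pred_a, pred_b, gene_a=a, gene_b=b)
                else:
                    v_gen = genetic_interaction_test(
                        obs_a, pred_a, np.zeros_like(obs_a), gene_a=a, gene_b=b
                    )
                mB = models.get(b)
                snps_b = mB.nonzero_snps if mB is not None and mB.trainable else []
                try:
                    gB = c.genotypes.restrict(snps_b).dosage_frame() if snps_b else pd.DataFrame(index=c.expression.index)
                    v_eqtl = geneB_eqtl_adjusted_test(obs_a, pred_a, obs_b, gB, gene_a=a, gene_b=b)
                    verdicts_c = [v_snp, v_third, v_gen, v_eqtl]
                except ValueError:
                    verdicts_c = [v_snp, v_third, v_gen]
                for v in verdicts_c:
                    verdict_rows.append(
                        {
                            "gene_a": v.gene_a, "gene_b": v.gene_b, "cohort": name,
                            "kind": v.kind, "flagged": v.flagged,
                            "explaining_id": v.explaining_id or "",
                            "interaction_p": v.interaction_p,
                            "interaction_fdr": v.interaction_fdr,
                            "untestable": v.untestable,
                        }
                    )
                if v_snp.flagged:
                    snp_flagged.add((a, b))
                if v_third.flagged:
                    third_flagged.add((a, b))
    verdicts = pd.DataFrame(verdict_rows)
    funnel["pairs_snp_explained"] = len(snp_flagged)
    funnel["pairs_third_gene_explained"] = len(third_flagged)

    removed = snp_flagged | third_flagged
    if len(replicated):
        keep_mask = [
            (a, b) not in removed for a, b in zip(replicated["gene_a"], replicated["gene_b"])
        ]
        putative = replicated.loc[keep_mask].reset_index(drop=True)
    else:
        putative = replicated
    funnel["pairs_putative"] = len(putative)
    # set identity the stage structure promises
    assert len(putative) == len(replicated) - len(
        removed & set(rep_pairs)
    ), "putative set must equal replicated minus snp- and third-gene-explained"

    # --- variance decomposition -------------------------------------------
    var_rows = []
    step_rows = []
    if cfg.run_variance and len(putative):
        put_pairs = list(zip(putative["gene_a"], putative["gene_b"]))
        for name in (cohort1.name, cohort2.name):
            for a, b in put_pairs:
                d = pseudo_r2_decomposition(
                    resid[name][a].to_numpy(), pred_frames[name][a].to_numpy(),
                    resid[name][b].to_numpy(), gene_a=a, gene_b=b,
                )
                var_rows.append(
                    {
                        "gene_a": a, "gene_b": b, "cohort": name,
                        "r2_cis": d.r2_cis, "r2_main": d.r2_main, "r2_full": d.r2_full,
                        "main_increment": d.main_increment,
                        "interaction_increment": d.interaction_increment,
                    }
                )
        by_a: dict[str, list[str]] = {}
        for a, b in put_pairs:
            by_a.setdefault(a, []).append(b)
        for a, bs in sorted(by_a.items()):
            if len(bs) < 2:
                continue
            for name in (cohort1.name, cohort2.name):
                kept = prune_correlated(resid[name][bs], cutoff=cfg.correlation_cutoff)
                if len(kept) < 2:
                    continue
                summ = stepwise_variance(
                    resid[name][a].to_numpy(), pred_frames[name][a].to_numpy(),
                    resid[name][kept],
                    iterations=cfg.stepwise_iterations, train_frac=cfg.train_frac,
                    seed=stage_seed(cfg.seed, f"stepwise:{name}:{a}"), gene_a=a,
                )
                step_rows.append(
                    {
                        "gene_a": a, "cohort": name, "n_partners": len(kept),
                        "n_iterations": summ.n_iterations, "n_skipped": summ.n_skipped,
                        "r2_cis_train_mean": summ.r2_cis_train_mean,
                        "r2_full_train_mean": summ.r2_full_train_mean,
                        "r2_full_test_mean": summ.r2_full_test_mean,
                        "r2_full_test_median": summ.r2_full_test_median,
                        "r2_full_test_sd": summ.r2_full_test_sd,
                        "r2_main_test_mean": summ.r2_main_test_mean,
                        "r2_interaction_test_mean": summ.r2_interaction_test_mean,
                        "r2_interaction_test_median": summ.r2_interaction_test_median,
                        "r2_interaction_test_sd": summ.r2_interaction_test_sd,
                    }
                )
    variance = pd.DataFrame(var_rows)
    stepwise = pd.DataFrame(step_rows)

    # --- enrichment ---------------------------------------------------------
    enrichment = None
    if gene_sets and len(putative):
        foreground = sorted(set(putative["gene_b"]))
        background = sorted({b for _, b in pairs})
        enrichment = hypergeometric_enrichment(foreground, background, gene_sets)

    return PipelineResult(
        retention=retention, retained_genes=retained_genes,
        veqtl=veqtl_tables, veqtl_replicated=veqtl_replicated,
        scans=scans, replicated=replicated, concordance=concordance,
        coexpression=coexpr, verdicts=verdicts, putative=putative,
        variance=variance, stepwise=stepwise, enrichment=enrichment,
        funnel=funnel, models=models,
    )


def write_results(result: PipelineResult, outdir) -> None:
    """Write every result table plus a JSON manifest to ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    vio.write_table(result.retention, out / "retention.tsv")
    vio.write_table(pd.concat(result.veqtl.values(), ignore_index=True), out / "veqtl.tsv")
    vio.write_table(pd.concat(result.scans.values(), ignore_index=True), out / "interactions.tsv")
    vio.write_table(result.replicated, out / "replicated_pairs.tsv")
    vio.write_table(result.coexpression, out / "coexpression.tsv")
    vio.write_table(result.verdicts, out / "confounder_verdicts.tsv")
    vio.write_table(result.putative, out / "putative_pairs.tsv")
    vio.write_table(result.variance, out / "variance_decomposition.tsv")
    vio.write_table(result.stepwise, out / "stepwise_summary.tsv")
    if result.enrichment is not None:
        vio.write_table(result.enrichment, out / "enrichment.tsv")
    vio.write_model_store(result.models, out / "cis_weights.tsv", out / "cis_models.json")
    manifest = {
        "funnel": result.funnel,
        "veqtl_replicated": result.veqtl_replicated,
        "concordance": {
            k: (v if not isinstance(v, float) or np.isfinite(v) else None)
            for k, v in result.concordance.items()
        },
        "tables": sorted(p.name for p in out.glob("*.tsv")),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
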