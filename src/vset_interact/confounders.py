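"""Confounder exclusion for replicated interaction pairs.

A replicated pair may be an artefact: the apparent gene B interaction
could be driven by a single SNP near gene A, by the expression of a third
gene C that gene B merely proxies, or by gene B's own cis-genetic
component.  Each test refits the interaction model with the candidate
covariate added (one at a time) — both its main effect and its own
interaction with pred_A, so that a candidate which truly carries the
interaction can absorb it — and asks whether the pred_A x obs_B term
remains significant.  "Loses significance" means the BH-adjusted
interaction p across a pair's candidate refits reaches 0.05 for at least
one candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._ols import nested_f_test
from .veqtl import bh_fdr

__all__ = [
    "ConfounderVerdict",
    "snp_confounder_test",
    "third_gene_test",
    "genetic_interaction_test",
    "geneB_eqtl_adjusted_test",
]

FDR_THRESHOLD = 0.05


@dataclass
class ConfounderVerdict:
    """Outcome of one confounder family for one pair."""

    gene_a: str
    gene_b: str
    kind: str  # snp | third_gene | genetic | eqtl_adjusted
    flagged: bool
    explaining_id: str | None = None
    interaction_p: float = np.nan  # worst (largest) adjusted p across candidates
    interaction_fdr: float = np.nan
    residual_df: int = -1
    untestable: bool = False
    skipped: list[str] = field(default_factory=list)


def _interaction_p_with_covariates(
    obs_a: np.ndarray, pred_a: np.ndarray, obs_b: np.ndarray, covs: np.ndarray | None
) -> tuple[float, int]:
    """F-test p for the pred_A x obs_B term with extra covariates in both models."""
    n = len(obs_a)
    base = [np.ones(n), pred_a, obs_b]
    if covs is not None and covs.size:
        base.append(covs)
    X_reduced = np.column_stack(base)
    X_full = np.column_stack([X_reduced, pred_a * obs_b])
    F, p, _, _ = nested_f_test(X_full, X_reduced, obs_a)
    rank = np.linalg.matrix_rank(X_full)
    return p, n - rank


def snp_confounder_test(
    obs_a, pred_a, obs_b, window_dosages: pd.DataFrame, gene_a: str = "A", gene_b: str = "B"
) -> ConfounderVerdict:
    """Can any single SNP in gene A's cis window explain the interaction?

    The interaction model is refitted once per window SNP, adding the
    SNP's dosage and its pred_A interaction as covariates.  Monomorphic
    SNPs are skipped.  With an empty window the verdict is vacuously
    "retained".
    """
    obs_a = np.asarray(obs_a, dtype=float)
    pred_a = np.asarray(pred_a, dtype=float)
    obs_b = np.asarray(obs_b, dtype=float)
    pvals, ids, skipped = [], [], []
    for snp in window_dosages.columns:
        d = window_dosages[snp].to_numpy(dtype=float)
        if np.ptp(d) == 0.0:
            skipped.append(str(snp))
            continue
        covs = np.column_stack([d, pred_a * d])
        p, _ = _interaction_p_with_covariates(obs_a, pred_a, obs_b, covs)
        pvals.append(p)
        ids.append(str(snp))
    return _verdict_from_candidates(gene_a, gene_b, "snp", pvals, ids, skipped)


def third_gene_test(
    obs_a, pred_a, obs_b, candidates: pd.DataFrame, gene_a: str = "A", gene_b: str = "B"
) -> ConfounderVerdict:
    """Can the observed expression of a third gene C explain the interaction?

    ``candidates`` holds obs_C columns (C not in {A, B} — columns named A or
    B, or collinear with obs_B, are skipped).
    """
    obs_a = np.asarray(obs_a, dtype=float)
    pred_a = np.asarray(pred_a, dtype=float)
    obs_b = np.asarray(obs_b, dtype=float)
    pvals, ids, skipped = [], [], []
    for c in candidates.columns:
        if c in (gene_a, gene_b):
            skipped.append(str(c))
            continue
        x = candidates[c].to_numpy(dtype=float)
        if np.ptp(x) == 0.0 or abs(np.corrcoef(x, obs_b)[0, 1]) > 0.999:
            skipped.append(str(c))
            continue
        covs = np.column_stack([x, pred_a * x])
        p, _ = _interaction_p_with_covariates(obs_a, pred_a, obs_b, covs)
        pvals.append(p)
        ids.append(str(c))
    return _verdict_from_candidates(gene_a, gene_b, "third_gene", pvals, ids, skipped)


def _verdict_from_candidates(
    gene_a: str, gene_b: str, kind: str, pvals: list[float], ids: list[str], skipped: list[str]
) -> ConfounderVerdict:
    if not pvals:
        return ConfounderVerdict(
            gene_a=gene_a, gene_b=gene_b, kind=kind, flagged=False, skipped=skipped
        )
    fdr = bh_fdr(np.asarray(pvals))
    worst = int(np.argmax(fdr))
    flagged = bool(fdr[worst] >= FDR_THRESHOLD)
    return ConfounderVerdict(
        gene_a=gene_a,
        gene_b=gene_b,
        kind=kind,
        flagged=flagged,
        explaining_id=ids[worst] if flagged else None,
        interaction_p=float(pvals[worst]),
        interaction_fdr=float(fdr[worst]),
        skipped=skipped,
    )


def genetic_interaction_test(
    obs_a, pred_a, pred_b, gene_a: str = "A", gene_b: str = "B"
) -> ConfounderVerdict:
    """Is the interaction genetic–genetic (predicted x predicted)?

    Fits ``obs_A ~ pred_A + pred_B + pred_A * pred_B`` and reports the
    interaction term's F-test p.  ``flagged`` is True when the genetic
    channel is itself significant (p < 0.05 here; adjust across pairs
    before labelling a pair "genetic" in both cohorts).  A constant
    ``pred_b`` (no cis model) makes the pair untestable.
    """
    obs_a = np.asarray(obs_a, dtype=float)
    pred_a = np.asarray(pred_a, dtype=float)
    pred_b = np.asarray(pred_b, dtype=float)
    if np.ptp(pred_b) == 0.0:
        return ConfounderVerdict(
            gene_a=gene_a, gene_b=gene_b, kind="genetic", flagged=False, untestable=True
        )
    n = len(obs_a)
    X_reduced = np.column_stack([np.ones(n), pred_a, pred_b])
    X_full = np.column_stack([X_reduced, pred_a * pred_b])
    F, p, _, _ = nested_f_test(X_full, X_reduced, obs_a)
    rank = np.linalg.matrix_rank(X_full)
    return ConfounderVerdict(
        gene_a=gene_a, gene_b=gene_b, kind="genetic",
        flagged=bool(np.isfinite(p) and p < 0.05),
        interaction_p=float(p), residual_df=n - rank,
    )


def geneB_eqtl_adjusted_test(
    obs_a,
    pred_a,
    obs_b,
    geneB_model_dosages: pd.DataFrame,
    gene_a: str = "A",
    gene_b: str = "B",
) -> ConfounderVerdict:
    """Does the interaction survive adjusting for gene B's cis eQTLs?

    The interaction model is extended with a main-effect and a
    pred_A-interaction term for *every* SNP in gene B's cis model, jointly.
    With zero model SNPs this reduces exactly to the plain interaction
    test.  Raises if the residual degrees of freedom would be exhausted.
    """
    obs_a = np.asarray(obs_a, dtype=float)
    pred_a = np.asarray(pred_a, dtype=float)
    obs_b = np.asarray(obs_b, dtype=float)
    n = len(obs_a)
    S = geneB_model_dosages.to_numpy(dtype=float) if len(geneB_model_dosages.columns) else None
    if S is not None:
        poly = np.ptp(S, axis=0) > 0
        S = S[:, poly]
        if S.shape[1] == 0:
            S = None
    extra = None
    if S is not None:
        extra = np.column_stack([S, pred_a[:, None] * S])
    n_params = 4 + (extra.shape[1] if extra is not None else 0)
    if n - n_params <= 0:
        raise ValueError(
            f"overfit: too many gene B model SNPs ({0 if S is None else S.shape[1]}) for n={n}"
        )
    p, resid_df = _interaction_p_with_covariates(obs_a, pred_a, obs_b, extra)
    return ConfounderVerdict(
        gene_a=gene_a, gene_b=gene_b, kind="eqtl_adjusted",
        flagged=bool(np.isfinite(p) and p >= FDR_THRESHOLD),
        interaction_p=float(p), residual_df=resid_df,
    )
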