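"""Genome-wide variant-set x distal-gene interaction scan and replication.

For each focal gene A (with a validated cis model) and each distal gene B,
the model

``obs_A ~ beta_0 + beta_a * pred_A + beta_b * obs_B + beta_ab * pred_A * obs_B``

is fitted by OLS and the interaction term is tested with an ANOVA F-test
against the no-interaction nested model.  Discoveries must replicate in a
second cohort — significant after multiple-testing correction within the
replication attempt *and* with a concordant interaction-coefficient sign.
A chi-squared test compares the sign-combination distribution of
significant pairs against all tested pairs, and a Pearson co-expression
test quantifies how much ordinary correlation the interacting pairs show.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._ols import nested_f_test, ols_fit
from .veqtl import bh_fdr

__all__ = [
    "InteractionRecord",
    "ConcordanceTable",
    "interaction_test",
    "scan_pairs",
    "scan_and_replicate",
    "sign_concordance_chisq",
    "coexpression_test",
    "coexpression_table",
]

SIGN_COMBOS = ("-/-", "-/+", "+/-", "+/+")


@dataclass
class InteractionRecord:
    """One gene A x gene B interaction test."""

    gene_a: str
    gene_b: str
    beta_0: float
    beta_a: float
    beta_b: float
    beta_ab: float
    f_stat: float
    p: float
    n: int
    cohort: str = ""
    fdr: float = np.nan
    untestable: bool = False

    @property
    def sign(self) -> str:
        return "+" if self.beta_ab > 0 else "-"


def interaction_test(
    obs_a, pred_a, obs_b, gene_a: str = "A", gene_b: str = "B", cohort: str = ""
) -> InteractionRecord:
    """Fit the interaction model for one pair and F-test the product term.

    Preconditions: aligned vectors, non-constant ``pred_a`` and ``obs_b``,
    and ``gene_b != gene_a``.  Near-collinear inputs
    (``|r(pred_a, obs_b)| > 0.999``) give a record flagged ``untestable``.
    """
    obs_a = np.asarray(obs_a, dtype=float)
    pred_a = np.asarray(pred_a, dtype=float)
    obs_b = np.asarray(obs_b, dtype=float)
    n = len(obs_a)
    if not (len(pred_a) == len(obs_b) == n):
        raise ValueError("inputs must be aligned")
    if gene_a == gene_b:
        raise ValueError("gene B must differ from gene A")
    if np.ptp(pred_a) == 0.0:
        raise ValueError("predicted expression of gene A is constant")
    if np.ptp(obs_b) == 0.0:
        raise ValueError("observed expression of gene B is constant")
    r = np.corrcoef(pred_a, obs_b)[0, 1]
    if abs(r) > 0.999:
        return InteractionRecord(
            gene_a=gene_a, gene_b=gene_b, beta_0=np.nan, beta_a=np.nan,
            beta_b=np.nan, beta_ab=np.nan, f_stat=np.nan, p=np.nan, n=n,
            cohort=cohort, untestable=True,
        )
    X_full = np.column_stack([np.ones(n), pred_a, obs_b, pred_a * obs_b])
    beta, _, _ = ols_fit(X_full, obs_a)
    F, p, _, _ = nested_f_test(X_full, X_full[:, :3], obs_a)
    return InteractionRecord(
        gene_a=gene_a, gene_b=gene_b, beta_0=float(beta[0]), beta_a=float(beta[1]),
        beta_b=float(beta[2]), beta_ab=float(beta[3]), f_stat=F, p=p, n=n, cohort=cohort,
    )


def scan_pairs(
    observed: pd.DataFrame,
    predictions: pd.DataFrame,
    pairs: list[tuple[str, str]],
    cohort: str = "",
) -> pd.DataFrame:
    """Run :func:`interaction_test` for each (gene A, gene B) pair.

    Returns a table with one row per pair; BH-FDR is computed across the
    testable pairs of this scan.
    """
    records = []
    for a, b in pairs:
        rec = interaction_test(
            observed[a].to_numpy(), predictions[a].to_numpy(), observed[b].to_numpy(),
            gene_a=a, gene_b=b, cohort=cohort,
        )
        records.append(rec)
    table = pd.DataFrame(
        {
            "gene_a": [r.gene_a for r in records],
            "gene_b": [r.gene_b for r in records],
            "beta_0": [r.beta_0 for r in records],
            "beta_a": [r.beta_a for r in records],
            "beta_b": [r.beta_b for r in records],
            "beta_ab": [r.beta_ab for r in records],
            "f_stat": [r.f_stat for r in records],
            "p": [r.p for r in records],
            "n": [r.n for r in records],
            "untestable": [r.untestable for r in records],
            "cohort": cohort,
        }
    )
    ok = ~table["untestable"]
    table["fdr"] = np.nan
    if ok.any():
        table.loc[ok, "fdr"] = bh_fdr(table.loc[ok, "p"].to_numpy())
    table["sign"] = np.where(table["beta_ab"] > 0, "+", "-")
    return table


def scan_and_replicate(
    records1: pd.DataFrame, records2: pd.DataFrame, fdr: float = 0.05
) -> pd.DataFrame:
    """Two-cohort replication with sign concordance.

    A pair is replicated when it is significant in cohort 1 (BH-FDR within
    cohort 1's tested set), significant again in cohort 2 with the FDR
    recomputed over only the cohort-1-significant pairs (the replication
    test burden), and the interaction coefficient has the same sign in both
    cohorts.  An exactly-zero coefficient is treated as discordant.
    """
    for df in (records1, records2):
        for col in ("gene_a", "gene_b", "p", "beta_ab"):
            if col not in df.columns:
                raise ValueError(f"records lack column {col!r}")
    r1 = records1.loc[~records1.get("untestable", False)].copy()
    r2 = records2.loc[~records2.get("untestable", False)].copy()
    if len(r1) == 0 or len(r2) == 0:
        raise ValueError("empty overlap of tested pairs")
    r1["fdr1"] = bh_fdr(r1["p"].to_numpy())
    sig1 = r1[r1["fdr1"] < fdr]
    if len(sig1) == 0:
        return pd.DataFrame(
            columns=["gene_a", "gene_b", "beta_ab_1", "beta_ab_2", "fdr1", "fdr2", "sign"]
        )
    key = ["gene_a", "gene_b"]
    merged = sig1.merge(r2, on=key, suffixes=("_1", "_2"))
    if len(merged) == 0:
        return pd.DataFrame(
            columns=["gene_a", "gene_b", "beta_ab_1", "beta_ab_2", "fdr1", "fdr2", "sign"]
        )
    merged["fdr2"] = bh_fdr(merged["p_2"].to_numpy())
    concordant = (
        (merged["fdr2"] < fdr)
        & (np.sign(merged["beta_ab_1"]) == np.sign(merged["beta_ab_2"]))
        & (merged["beta_ab_1"] != 0.0)
        & (merged["beta_ab_2"] != 0.0)
    )
    out = merged.loc[
        concordant, key + ["beta_ab_1", "beta_ab_2", "p_1", "p_2", "fdr1", "fdr2"]
    ].copy()
    out["sign"] = np.where(out["beta_ab_1"] > 0, "+", "-")
    return out.reset_index(drop=True)


@dataclass
class ConcordanceTable:
    """Counts of interaction-sign combinations across the two cohorts."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        missing = set(SIGN_COMBOS) - set(self.counts)
        if missing:
            raise ValueError(f"missing sign combinations: {sorted(missing)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_signs(cls, signs1, signs2) -> "ConcordanceTable":
        counts = dict.fromkeys(SIGN_COMBOS, 0)
        for s1, s2 in zip(signs1, signs2):
            counts[f"{s1}/{s2}"] += 1
        return cls(counts=counts)

    def as_array(self) -> np.ndarray:
        return np.array([self.counts[c] for c in SIGN_COMBOS], dtype=float)

    @property
    def total(self) -> int:
        return int(self.as_array().sum())


def sign_concordance_chisq(
    sig: ConcordanceTable, all_pairs: ConcordanceTable
) -> tuple[float, int, float]:
    """Pearson chi-squared test of significant-pair sign combinations.

    Expected counts are the all-tested-pairs sign proportions scaled to the
    significant-pair total; df = 3.
    """
    obs = sig.as_array()
    ref = all_pairs.as_array()
    if np.any(ref == 0):
        raise ValueError("all four sign combinations must be populated in the reference")
    exp = ref / ref.sum() * obs.sum()
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    df = 3
    return chi2, df, float(stats.chi2.sf(chi2, df))


def coexpression_test(obs_a, obs_b) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between two observed profiles."""
    obs_a = np.asarray(obs_a, dtype=float)
    obs_b = np.asarray(obs_b, dtype=float)
    if len(obs_a) != len(obs_b):
        raise ValueError("inputs must be aligned")
    if len(obs_a) < 10:
        raise ValueError("need at least 10 individuals")
    if np.ptp(obs_a) == 0.0 or np.ptp(obs_b) == 0.0:
        raise ValueError("zero-variance expression vector")
    r, p = stats.pearsonr(obs_a, obs_b)
    return float(r), float(p)


def coexpression_table(observed: pd.DataFrame, pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Co-expression of a pair set with BH-FDR and summary columns."""
    rows = []
    for a, b in pairs:
        r, p = coexpression_test(observed[a].to_numpy(), observed[b].to_numpy())
        rows.append({"gene_a": a, "gene_b": b, "r": r, "p": p})
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = bh_fdr(table["p"].to_numpy())
        table.attrs["mean_r"] = float(table["r"].mean())
        table.attrs["mean_abs_r"] = float(table["r"].abs().mean())
        table.attrs["mean_r2"] = float((table["r"] ** 2).mean())
    return table
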