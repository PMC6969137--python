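"""Variant-set veQTL detection: variance of expression that tracks the cis score.

If a gene's expression involves an interaction between its cis-regulatory
variants and some other factor, the *variance* of expression differs
between individuals carrying different variant-sets even when the factor
itself is unobserved.  The test regresses observed expression on the
cis-genetic prediction, then rank-correlates the prediction with the
squared residuals: a monotone association means variant-set-dependent
variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._ols import ols_fit

__all__ = ["VeqtlResult", "veqtl_test", "bh_fdr", "veqtl_scan"]


@dataclass
class VeqtlResult:
    gene: str
    rho: float
    p: float
    n: int
    fdr: float = np.nan
    undefined: bool = False


def veqtl_test(pred_a, obs_a, gene: str = "") -> VeqtlResult:
    """Test for variant-set-dependent variance in one gene's expression.

    ``obs_a`` is regressed on ``pred_a`` (intercept + slope); Spearman's
    rank correlation between ``pred_a`` and the squared residuals is
    returned with its two-sided p-value (t approximation, average ranks for
    ties).

    Raises on ``n < 10`` or a constant prediction.  Identically-zero
    residuals (deterministic obs = pred) yield a result flagged
    ``undefined`` that must be excluded from FDR adjustment.
    """
    pred_a = np.asarray(pred_a, dtype=float)
    obs_a = np.asarray(obs_a, dtype=float)
    n = len(pred_a)
    if n != len(obs_a):
        raise ValueError("pred and obs must be aligned")
    if n < 10:
        raise ValueError(f"need at least 10 individuals, got {n}")
    if np.ptp(pred_a) == 0.0:
        raise ValueError("predicted expression is constant")

    X = np.column_stack([np.ones(n), pred_a])
    beta, _, _ = ols_fit(X, obs_a)
    resid = obs_a - X @ beta
    sq = resid**2
    if np.allclose(sq, 0.0):
        return VeqtlResult(gene=gene, rho=np.nan, p=np.nan, n=n, undefined=True)
    rho, p = stats.spearmanr(pred_a, sq)
    return VeqtlResult(gene=gene, rho=float(rho), p=float(p), n=n)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (R ``p.adjust(method="BH")``)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def veqtl_scan(
    predictions: pd.DataFrame, observed: pd.DataFrame, genes=None
) -> pd.DataFrame:
    """Run :func:`veqtl_test` per gene and BH-adjust across defined tests."""
    genes = list(genes) if genes is not None else list(predictions.columns)
    results = [
        veqtl_test(predictions[g].to_numpy(), observed[g].to_numpy(), gene=g) for g in genes
    ]
    table = pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "rho": [r.rho for r in results],
            "p": [r.p for r in results],
            "n": [r.n for r in results],
            "undefined": [r.undefined for r in results],
        }
    )
    ok = ~table["undefined"]
    table["fdr"] = np.nan
    if ok.any():
        table.loc[ok, "fdr"] = bh_fdr(table.loc[ok, "p"].to_numpy())
    return table
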