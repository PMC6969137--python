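"""Covariate/batch regression, hidden-factor removal and kurtosis filtering.

Expression is cleaned in three stages before any association testing:

1. :func:`regress_covariates` removes fixed effects (sex, age, ancestry PCs)
   by least squares and batch factors (plate, array) as shrunken random
   intercepts, probe by probe.
2. :func:`remove_hidden_factors` regresses out data-driven expression-wide
   factors (principal components), with the number of factors chosen by a
   permutation (parallel-analysis) criterion.
3. :func:`kurtosis_filter` drops genes whose distribution is too
   heavy-tailed for moment-based interaction tests.

The residuals of stage 1+2 stand in for observed expression everywhere
downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ResidualExpression",
    "KurtosisPartition",
    "kurtosis",
    "kurtosis_filter",
    "regress_covariates",
    "remove_hidden_factors",
]


@dataclass
class ResidualExpression:
    """Individuals x probes residual expression plus a removal record."""

    values: pd.DataFrame
    fixed_effects: list[str] = field(default_factory=list)
    batch_factors: list[str] = field(default_factory=list)
    n_hidden_factors: int = 0

    @property
    def individuals(self) -> list[str]:
        return list(self.values.index)

    @property
    def probes(self) -> list[str]:
        return list(self.values.columns)


def _split_covariates(cov: pd.DataFrame) -> tuple[list[str], list[str]]:
    fixed, batch = [], []
    for col in cov.columns:
        if pd.api.types.is_numeric_dtype(cov[col]):
            fixed.append(col)
        else:
            batch.append(col)
    return fixed, batch


def _check_design(X: np.ndarray, names: list[str]) -> None:
    """Fail loudly on rank-deficient fixed-effect designs, naming a culprit."""
    for j, name in enumerate(names):
        if np.ptp(X[:, j + 1]) == 0.0:  # column 0 is the intercept
            raise ValueError(f"fixed-effect covariate {name!r} is constant")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # find the first column whose addition does not increase the rank
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
                raise ValueError(
                    f"fixed-effect design is rank deficient at covariate {names[j - 1]!r}"
                )
        raise ValueError("fixed-effect design is rank deficient")


def _remove_batch(resid: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Subtract shrunken random-intercept estimates for one batch factor.

    Method-of-moments one-way variance components per probe: the group mean
    is shrunk by ``sigma_b^2 / (sigma_b^2 + sigma_e^2 / n_k)``.  Shrinkage
    is only applied to probes where the between-group mean square exceeds
    its null expectation (one-way ANOVA F beyond the 95th percentile), so
    pure-noise batch structure is left untouched and the operation is
    idempotent.
    """
    from scipy import stats

    codes, uniq = pd.factorize(labels)
    K = len(uniq)
    if K < 2:
        return resid
    N, P = resid.shape
    n_k = np.bincount(codes, minlength=K).astype(float)
    group_sums = np.zeros((K, P))
    np.add.at(group_sums, codes, resid)
    group_means = group_sums / n_k[:, None]
    grand = resid.mean(axis=0, keepdims=True)

    ss_between = (n_k[:, None] * (group_means - grand) ** 2).sum(axis=0)
    within = resid - group_means[codes]
    ss_within = (within**2).sum(axis=0)
    df_b, df_w = K - 1, N - K
    if df_w <= 0:
        return resid
    msb = ss_between / df_b
    msw = ss_within / df_w
    # effective group size for the MoM between-group variance component
    n0 = (N - (n_k**2).sum() / N) / df_b
    sigma_b2 = np.maximum(0.0, (msb - msw) / n0)

    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(msw > 0, msb / msw, 0.0)
    gate = F > stats.f.ppf(0.95, df_b, df_w)
    sigma_b2 = np.where(gate, sigma_b2, 0.0)

    lam = sigma_b2[None, :] / (sigma_b2[None, :] + msw[None, :] / n_k[:, None])
    lam = np.nan_to_num(lam)
    pred = lam * (group_means - grand)
    return resid - pred[codes]


def regress_covariates(expr: pd.DataFrame, cov: pd.DataFrame) -> ResidualExpression:
    """Remove fixed covariate effects and batch random intercepts per probe.

    Parameters
    ----------
    expr
        Individuals x probes expression, index aligned with ``cov``.
    cov
        One row per individual.  Numeric columns (sex, age, PCs) are fitted
        as fixed effects with an intercept; string/categorical columns
        (plate, array) as random intercepts, removed sequentially by
        method-of-moments shrinkage.  The fixed/batch removal is iterated
        to its fixed point, so applying the function to its own output is
        a no-op.

    Returns
    -------
    ResidualExpression
        Residuals with column means ~ 0 and a record of what was removed.
    """
    if list(expr.index) != list(cov.index):
        raise ValueError("expression and covariate tables must share the individual index")
    fixed, batch = _split_covariates(cov)
    for b in batch:
        counts = cov[b].value_counts()
        if (counts < 1).any() or len(counts) == 0:
            raise ValueError(f"batch factor {b!r} has empty levels")

    n = len(expr)
    X = np.column_stack([np.ones(n)] + [cov[c].to_numpy(dtype=float) for c in fixed])
    _check_design(X, fixed)
    XtX_inv_Xt = np.linalg.pinv(X)
    resid = expr.to_numpy(dtype=float)
    for _ in range(50):
        prev = resid
        resid = resid - X @ (XtX_inv_Xt @ resid)
        for b in batch:
            resid = _remove_batch(resid, cov[b].to_numpy())
        if np.max(np.abs(resid - prev)) < 1e-13:
            break
    resid = resid - resid.mean(axis=0, keepdims=True)
    return ResidualExpression(
        values=pd.DataFrame(resid, index=expr.index, columns=expr.columns),
        fixed_effects=fixed,
        batch_factors=batch,
    )


def remove_hidden_factors(
    resid: ResidualExpression | pd.DataFrame,
    k_max: int,
    n_permutations: int = 99,
    seed: int = 0,
) -> ResidualExpression:
    """Regress out data-driven global expression factors.

    Probes are centred and scaled to unit variance (so no single
    high-variance probe can masquerade as a global factor) and decomposed
    by SVD; the number of factors ``k <= k_max`` is chosen by a permutation
    criterion in the spirit of Buja & Eyuboglu's parallel analysis:
    factors are retained while the observed eigenvalue exceeds the 95th
    percentile of the same-rank eigenvalues obtained after independently
    permuting each column.  The retained individual-space factors are then
    projected out of every (unscaled) probe.

    ``k_max <= 0`` is a no-op (with a warning).
    """
    values = resid.values if isinstance(resid, ResidualExpression) else resid
    if k_max <= 0:
        warnings.warn("k_max <= 0: hidden-factor removal skipped", stacklevel=2)
        out = values.copy()
        k = 0
    else:
        n, p = values.shape
        if k_max >= min(n, p):
            raise ValueError("k_max must be smaller than min(n_individuals, n_probes)")
        Y = values.to_numpy(dtype=float)
        Y = Y - Y.mean(axis=0, keepdims=True)
        sds = Y.std(axis=0)
        Z = Y / np.where(sds > 0, sds, 1.0)
        U, S, _ = np.linalg.svd(Z, full_matrices=False)
        eig = S**2

        rng = np.random.default_rng(seed)
        k_top = min(k_max + 1, len(eig))
        perm_eigs = np.empty((n_permutations, k_top))
        for b in range(n_permutations):
            Zp = np.empty_like(Z)
            for j in range(p):
                Zp[:, j] = Z[rng.permutation(n), j]
            sp = np.linalg.svd(Zp, compute_uv=False)
            perm_eigs[b] = (sp**2)[:k_top]
        thresh = np.percentile(perm_eigs, 95, axis=0)

        k = 0
        while k < k_max and eig[k] > thresh[k]:
            k += 1
        if k > 0:
            Uk = U[:, :k]
            out_arr = Y - Uk @ (Uk.T @ Y)
        else:
            out_arr = Y
        out = pd.DataFrame(out_arr, index=values.index, columns=values.columns)

    if isinstance(resid, ResidualExpression):
        return ResidualExpression(
            values=out,
            fixed_effects=list(resid.fixed_effects),
            batch_factors=list(resid.batch_factors),
            n_hidden_factors=k,
        )
    return ResidualExpression(values=out, n_hidden_factors=k)


def kurtosis(x) -> float:
    """Pearson (non-excess) kurtosis ``m4 / m2^2`` with biased moments.

    A Gaussian sample gives ~3.  Matches the plain moment-ratio convention
    of R's ``moments::kurtosis``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("kurtosis requires at least 4 observations")
    d = x - x.mean()
    m2 = np.mean(d**2)
    if m2 == 0.0:
        return np.inf
    return float(np.mean(d**4) / m2**2)


@dataclass
class KurtosisPartition:
    retained: list[str]
    excluded: dict[str, str]  # gene -> reason
    kurtosis: dict[str, float]

    def __contains__(self, gene: str) -> bool:
        return gene in self.retained


def kurtosis_filter(values_by_gene, threshold: float = 9.0) -> KurtosisPartition:
    """Partition genes into retained / excluded by sample kurtosis.

    Parameters
    ----------
    values_by_gene
        DataFrame (individuals x genes) or mapping gene -> 1-D values.
    threshold
        Genes with ``m4/m2^2 > threshold`` are excluded.  The default of 9
        is deliberately permissive — three times the Gaussian value — so
        only clearly heavy-tailed genes are dropped.

    Zero-variance genes are excluded with reason ``"degenerate"``.
    """
    if isinstance(values_by_gene, pd.DataFrame):
        items = [(str(c), values_by_gene[c].to_numpy()) for c in values_by_gene.columns]
    else:
        items = [(str(g), np.asarray(v)) for g, v in values_by_gene.items()]
    retained, excluded, kvals = [], {}, {}
    for gene, vals in items:
        k = kurtosis(vals)
        kvals[gene] = k
        if not np.isfinite(k):
            excluded[gene] = "degenerate"
        elif k > threshold:
            excluded[gene] = f"kurtosis {k:.2f} > {threshold:g}"
        else:
            retained.append(gene)
    return KurtosisPartition(retained=retained, excluded=excluded, kurtosis=kvals)
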