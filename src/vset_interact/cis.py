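"""Per-gene elastic-net cis expression models and the lead-eQTL alternative.

A gene's regulatory variant-set is summarised by an elastic-net linear
model trained on the SNPs inside its cis window (1 Mb upstream of the TSS
to 1 Mb downstream of the TES).  The model's prediction is the gene's
cis-genetic expression component; genes are carried forward only when the
model predicts well in training cross-validation *and* transfers to an
independent cohort (squared correlation >= 0.1 in both) and the predicted
values pass the kurtosis filter.

:func:`lead_eqtl` provides the single-best-SNP alternative: the SNP with
the largest absolute marginal correlation, with a permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from .data import GenotypeMatrix
from .preprocess import kurtosis_filter

__all__ = [
    "CisWindow",
    "CisModel",
    "LeadEqtl",
    "cis_window",
    "fit_cis_model",
    "evaluate_transfer",
    "retain_genes",
    "lead_eqtl",
]

CIS_MARGIN = 1_000_000


@dataclass
class CisWindow:
    """Inclusive 1-based cis window [max(1, TSS - 1 Mb), TES + 1 Mb]."""

    gene: str
    chrom: str
    start: int
    end: int
    snp_ids: list[str]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"window start {self.start} > end {self.end}")


def cis_window(gene_annotation, snps: pd.DataFrame) -> CisWindow:
    """Build a gene's cis window and collect the member SNPs.

    Parameters
    ----------
    gene_annotation
        Mapping/row with ``gene``, ``chrom``, ``tss``, ``tes``.
    snps
        SNP table indexed by id with ``chrom`` and ``pos`` columns.
        Boundary SNPs (at exactly TSS - 1 Mb or TES + 1 Mb) are included.
    """
    g = gene_annotation
    tss, tes = int(g["tss"]), int(g["tes"])
    if tss > tes:
        raise ValueError(f"gene {g['gene']}: TSS {tss} > TES {tes}")
    chrom = g["chrom"]
    if chrom not in set(snps["chrom"]):
        raise ValueError(f"gene {g['gene']}: chromosome {chrom} absent from genotype data")
    start = max(1, tss - CIS_MARGIN)
    end = tes + CIS_MARGIN
    mask = (snps["chrom"] == chrom) & (snps["pos"] >= start) & (snps["pos"] <= end)
    return CisWindow(
        gene=str(g["gene"]), chrom=str(chrom), start=start, end=end,
        snp_ids=list(snps.index[mask]),
    )


@dataclass
class CisModel:
    """Elastic-net cis predictor: standardised-dosage weights + CV metrics."""

    gene: str
    snp_ids: list[str]
    weights: np.ndarray  # on the standardised-dosage scale
    intercept: float
    snp_means: np.ndarray
    snp_sds: np.ndarray
    cv_r2: float
    cv_p: float
    alpha: float = np.nan
    trainable: bool = True
    cv_fdr: float = np.nan
    transfer_r2: dict[str, float] = field(default_factory=dict)

    @property
    def nonzero_snps(self) -> list[str]:
        return [s for s, w in zip(self.snp_ids, self.weights) if w != 0.0]

    def predict(self, dosages, snp_ids=None, max_missing: float = 0.2) -> np.ndarray:
        """Predict expression from dosages (columns aligned to ``snp_ids``).

        SNPs absent from the target data are dropped; if more than
        ``max_missing`` of the model's nonzero-weight SNPs are missing the
        gene is flagged non-transferable via :class:`KeyError`.
        """
        if isinstance(dosages, GenotypeMatrix):
            frame = dosages.dosage_frame()
        elif isinstance(dosages, pd.DataFrame):
            frame = dosages
        else:
            frame = pd.DataFrame(np.asarray(dosages, dtype=float), columns=list(snp_ids))
        used = [s for s in self.snp_ids if s in frame.columns]
        needed = set(self.nonzero_snps)
        missing = needed - set(used)
        if needed and len(missing) / len(needed) > max_missing:
            raise KeyError(
                f"gene {self.gene}: {len(missing)}/{len(needed)} model SNPs missing "
                "in target cohort (non-transferable)"
            )
        idx = [self.snp_ids.index(s) for s in used]
        X = frame[used].to_numpy(dtype=float)
        X = _impute(X)
        sds = np.where(self.snp_sds[idx] > 0, self.snp_sds[idx], 1.0)
        Xs = (X - self.snp_means[idx]) / sds
        return Xs @ self.weights[idx] + self.intercept


def _impute(X: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages per SNP."""
    if np.isnan(X).any():
        X = X.copy()
        means = np.nanmean(X, axis=0)
        inds = np.where(np.isnan(X))
        X[inds] = np.take(means, inds[1])
    return X


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    X = _impute(np.asarray(X, dtype=float))
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    keep = sds > 0
    Xs = np.zeros_like(X)
    Xs[:, keep] = (X[:, keep] - means[keep]) / sds[keep]
    return Xs, means, sds, keep


def fit_cis_model(
    G,
    y,
    snp_ids=None,
    gene: str = "",
    folds: int = 10,
    mixing: float = 0.5,
    seed: int = 0,
    n_alphas: int = 50,
) -> CisModel:
    """Train an elastic-net cis model with k-fold cross-validation.

    Dosages are mean-imputed and standardised; the penalty strength is
    chosen by ``folds``-fold CV at the given ``mixing`` (l1 ratio, default
    0.5 following the PredictDB convention).  The reported ``cv_r2`` is the
    squared Pearson correlation between out-of-fold predictions and ``y``,
    with ``cv_p`` from the corresponding correlation test; significance
    across genes is assessed downstream by BH-FDR on ``cv_p``.

    An all-monomorphic window yields an untrainable model (empty weights).
    """
    if isinstance(G, GenotypeMatrix):
        snp_ids = G.snp_ids
        X = G.dosages
    else:
        X = np.asarray(G, dtype=float)
        snp_ids = list(snp_ids) if snp_ids is not None else [f"snp{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < folds:
        raise ValueError(f"n={n} below the number of CV folds ({folds})")

    Xs, means, sds, keep = _standardize(X)
    if not keep.any():
        return CisModel(
            gene=gene, snp_ids=list(snp_ids), weights=np.zeros(len(snp_ids)),
            intercept=float(np.mean(y)), snp_means=means, snp_sds=sds,
            cv_r2=0.0, cv_p=1.0, trainable=False,
        )

    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    enet_cv = ElasticNetCV(
        l1_ratio=mixing, alphas=n_alphas, cv=cv, max_iter=5000, tol=1e-7,
    )
    Xk = Xs[:, keep]
    enet_cv.fit(Xk, y)
    alpha = float(enet_cv.alpha_)

    # out-of-fold performance on a split independent of the one that chose
    # alpha, so the CV R^2 carries no selection optimism
    eval_cv = KFold(n_splits=folds, shuffle=True, random_state=seed + 1)
    oof = np.empty(n)
    for tr, te in eval_cv.split(Xk):
        m = ElasticNet(alpha=alpha, l1_ratio=mixing, max_iter=5000, tol=1e-7)
        m.fit(Xk[tr], y[tr])
        oof[te] = m.predict(Xk[te])
    if np.std(oof) == 0.0 or np.std(y) == 0.0:
        cv_r2, cv_p = 0.0, 1.0
    else:
        r, cv_p = stats.pearsonr(oof, y)
        cv_r2 = float(r**2) if r > 0 else 0.0
        if r <= 0:
            cv_p = 1.0  # anti-predictive CV models are not evidence of signal

    final = ElasticNet(alpha=alpha, l1_ratio=mixing, max_iter=5000, tol=1e-7)
    final.fit(Xk, y)
    weights = np.zeros(len(snp_ids))
    weights[keep] = final.coef_
    return CisModel(
        gene=gene, snp_ids=list(snp_ids), weights=weights,
        intercept=float(final.intercept_), snp_means=means, snp_sds=sds,
        cv_r2=cv_r2, cv_p=float(cv_p), alpha=alpha,
    )


def evaluate_transfer(model: CisModel, dosages, y, cohort: str = "external") -> float:
    """Squared Pearson correlation of model predictions with observed expression.

    Records the value in ``model.transfer_r2[cohort]`` and returns it.
    Raises :class:`KeyError` if too many model SNPs are missing (the gene
    is then non-transferable).
    """
    pred = model.predict(dosages)
    y = np.asarray(y, dtype=float)
    if np.std(pred) == 0.0 or np.std(y) == 0.0:
        r2 = 0.0
    else:
        r, _ = stats.pearsonr(pred, y)
        r2 = float(r**2)
    model.transfer_r2[cohort] = r2
    return r2


def retain_genes(
    models: dict[str, CisModel],
    predictions_by_cohort: dict[str, pd.DataFrame],
    r2_by_cohort: dict[str, dict[str, float]],
    r2_threshold: float = 0.1,
    kurtosis_threshold: float = 9.0,
    fdr_threshold: float = 0.05,
) -> tuple[set[str], pd.DataFrame]:
    """Apply the model-retention funnel and return (retained set, per-gene log).

    A gene survives when its CV performance is FDR-significant, its
    predicted values pass the kurtosis filter in every cohort, and its
    prediction R^2 is at least ``r2_threshold`` in every cohort (training
    CV and external transfer alike).  The kurtosis filter is applied before
    the R^2 gate.
    """
    from .veqtl import bh_fdr

    genes = sorted(models)
    pvals = np.array([models[g].cv_p for g in genes])
    fdr = bh_fdr(pvals)
    for g, q in zip(genes, fdr):
        models[g].cv_fdr = float(q)

    kurt_pass: dict[str, set[str]] = {}
    for cohort, preds in predictions_by_cohort.items():
        part = kurtosis_filter(preds, threshold=kurtosis_threshold)
        kurt_pass[cohort] = set(part.retained)

    rows = []
    retained = set()
    for g, q in zip(genes, fdr):
        m = models[g]
        reasons = []
        if not m.trainable:
            reasons.append("untrainable")
        if q >= fdr_threshold:
            reasons.append("cv_fdr")
        for cohort in predictions_by_cohort:
            if g in predictions_by_cohort[cohort].columns and g not in kurt_pass[cohort]:
                reasons.append(f"kurtosis:{cohort}")
        if not any(r.startswith("kurtosis") for r in reasons):
            for cohort, r2s in r2_by_cohort.items():
                if r2s.get(g, 0.0) < r2_threshold:
                    reasons.append(f"r2:{cohort}")
        ok = not reasons
        if ok:
            retained.add(g)
        rows.append(
            {
                "gene": g,
                "cv_r2": m.cv_r2,
                "cv_fdr": q,
                **{f"r2_{c}": r2s.get(g, np.nan) for c, r2s in r2_by_cohort.items()},
                "retained": ok,
                "reasons": ";".join(reasons),
            }
        )
    return retained, pd.DataFrame(rows)


@dataclass
class LeadEqtl:
    gene: str
    snp_id: str
    statistic: float  # absolute marginal correlation
    perm_p: float
    dosage_r2: float


def lead_eqtl(
    G, y, snp_ids=None, gene: str = "", n_perm: int = 1000, seed: int = 123456789
) -> LeadEqtl:
    """Single best cis SNP by absolute marginal correlation, with permutation p.

    The permutation p-value is ``(1 + #permutations with a better best
    statistic) / (1 + n_perm)``, permuting the phenotype.  ``dosage_r2`` is
    the R^2 of regressing ``y`` on the lead SNP's dosage.  Defaults (1000
    permutations, seed 123456789) follow common cis-eQTL mapping practice.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if isinstance(G, GenotypeMatrix):
        snp_ids = G.snp_ids
        X = G.dosages
    else:
        X = np.asarray(G, dtype=float)
        snp_ids = list(snp_ids) if snp_ids is not None else [f"snp{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    n = len(y)

    Xs, _, sds, keep = _standardize(X)
    if not keep.any():
        raise ValueError("no polymorphic SNP in the window")
    ys = (y - y.mean()) / y.std()
    corr = Xs.T @ ys / n
    corr[~keep] = 0.0
    best = int(np.argmax(np.abs(corr)))
    stat = float(np.abs(corr[best]))

    rng = np.random.default_rng(seed)
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    Yp = ys[perm_idx]  # n_perm x n
    perm_best = np.max(np.abs(Yp @ Xs / n), axis=1)
    p = (1 + int(np.sum(perm_best >= stat))) / (1 + n_perm)

    r2 = float(corr[best] ** 2)
    return LeadEqtl(gene=gene, snp_id=snp_ids[best], statistic=stat, perm_p=p, dosage_r2=r2)
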