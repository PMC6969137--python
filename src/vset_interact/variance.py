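"""Variance decomposition: how much expression variance do interactions explain?

Nested Gaussian models — cis-only, + distal main effect, + interaction —
are compared through pseudo-R^2 = (null deviance - residual deviance) /
null deviance (equal to the classical R^2 for least squares).  For genes
with two or more interaction partners, redundant partners are pruned by a
greedy correlation rule and a repeated stepwise-AIC regression over random
80/20 splits quantifies the joint contribution of the non-redundant set,
with the interaction-only share measured on the held-out test fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._ols import ols_fit, pseudo_r2

__all__ = [
    "VarianceDecomposition",
    "StepwiseSummary",
    "pseudo_r2_decomposition",
    "prune_correlated",
    "stepwise_variance",
]


@dataclass
class VarianceDecomposition:
    """Per-pair nested pseudo-R^2 decomposition."""

    gene_a: str
    gene_b: str
    r2_cis: float
    r2_main: float  # cumulative: cis + distal main effect
    r2_full: float  # cumulative: + interaction
    main_increment: float
    interaction_increment: float


def pseudo_r2_decomposition(
    obs_a, pred_a, obs_b, gene_a: str = "A", gene_b: str = "B"
) -> VarianceDecomposition:
    """Nested pseudo-R^2 of cis, distal main and interaction terms for one pair."""
    obs_a = np.asarray(obs_a, dtype=float)
    pred_a = np.asarray(pred_a, dtype=float)
    obs_b = np.asarray(obs_b, dtype=float)
    n = len(obs_a)
    if not (len(pred_a) == len(obs_b) == n):
        raise ValueError("inputs must be aligned")
    if np.ptp(pred_a) == 0.0 or np.ptp(obs_b) == 0.0:
        raise ValueError("degenerate (constant) predictor")
    ones = np.ones(n)
    X_cis = np.column_stack([ones, pred_a])
    X_main = np.column_stack([X_cis, obs_b])
    X_full = np.column_stack([X_main, pred_a * obs_b])
    _, rss_cis, _ = ols_fit(X_cis, obs_a)
    _, rss_main, _ = ols_fit(X_main, obs_a)
    _, rss_full, _ = ols_fit(X_full, obs_a)
    r2_cis = pseudo_r2(rss_cis, obs_a)
    r2_main = pseudo_r2(rss_main, obs_a)
    r2_full = pseudo_r2(rss_full, obs_a)
    return VarianceDecomposition(
        gene_a=gene_a, gene_b=gene_b, r2_cis=r2_cis, r2_main=r2_main, r2_full=r2_full,
        main_increment=r2_main - r2_cis, interaction_increment=r2_full - r2_main,
    )


def prune_correlated(obs_b: pd.DataFrame, cutoff: float = 0.4) -> list[str]:
    """Greedy removal of mutually correlated partner genes.

    While any pairwise ``|r|`` exceeds ``cutoff``, the member of a violating
    pair with the largest mean absolute correlation to the remaining set is
    dropped (ties broken by input order).  Deterministic given column order.
    """
    cols = list(obs_b.columns)
    if len(cols) < 1:
        raise ValueError("need at least one partner gene")
    if len(cols) == 1:
        return cols
    corr = obs_b.corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    alive = list(range(len(cols)))
    while True:
        sub = corr[np.ix_(alive, alive)]
        if sub.max() <= cutoff:
            break
        viol = np.any(sub > cutoff, axis=1)
        mean_abs = sub.mean(axis=1)
        cand = np.where(viol)[0]
        drop_local = cand[np.argmax(mean_abs[cand])]
        # argmax returns the first maximiser, so ties fall to input order
        del alive[int(drop_local)]
    return [cols[i] for i in alive]


@dataclass
class StepwiseSummary:
    """Across-iteration summary of repeated stepwise regression for one gene A."""

    gene_a: str
    n_iterations: int
    n_skipped: int
    r2_cis_train_mean: float
    r2_full_train_mean: float
    r2_full_test_mean: float
    r2_full_test_median: float
    r2_full_test_sd: float
    r2_main_test_mean: float
    r2_interaction_test_mean: float
    r2_interaction_test_median: float
    r2_interaction_test_sd: float
    selection_freq: dict[str, float] = field(default_factory=dict)
    iterations: pd.DataFrame | None = None


def _aic(rss: float, n: int, n_params: int) -> float:
    # R's stats::step AIC for lm, up to an additive constant
    return n * np.log(max(rss, 1e-300) / n) + 2 * (n_params + 1)


def _design(pred_a: np.ndarray, B: pd.DataFrame, terms: list[str]) -> np.ndarray:
    cols = [np.ones(len(pred_a)), pred_a]
    for t in terms:
        kind, name = t.split(":", 1)
        x = B[name].to_numpy(dtype=float)
        cols.append(x if kind == "b" else pred_a * x)
    return np.column_stack(cols)


def _stepwise(
    y: np.ndarray, pred_a: np.ndarray, B: pd.DataFrame, order: list[str]
) -> list[str]:
    """Bidirectional AIC stepwise between the cis-only and full interaction model.

    Terms are ``b:<gene>`` (main effect) and ``i:<gene>`` (interaction);
    marginality is respected — an interaction can only enter once its main
    effect is present, and a main effect can only leave after its
    interaction has.
    """
    n = len(y)
    terms: list[str] = []
    _, rss, rank = ols_fit(_design(pred_a, B, terms), y)
    current_aic = _aic(rss, n, rank)
    while True:
        moves: list[tuple[float, str, str]] = []
        present = set(terms)
        for g in order:
            if f"b:{g}" not in present:
                moves.append((0, "add", f"b:{g}"))
            elif f"i:{g}" not in present:
                moves.append((0, "add", f"i:{g}"))
        for t in terms:
            kind, g = t.split(":", 1)
            if kind == "i" or f"i:{g}" not in present:
                moves.append((0, "drop", t))
        best = None
        for _, action, term in moves:
            trial = terms + [term] if action == "add" else [t for t in terms if t != term]
            _, rss_t, rank_t = ols_fit(_design(pred_a, B, trial), y)
            aic_t = _aic(rss_t, n, rank_t)
            if best is None or aic_t < best[0]:
                best = (aic_t, action, term, trial)
        if best is None or best[0] >= current_aic - 1e-9:
            return terms
        current_aic, _, _, terms = best[0], best[1], best[2], best[3]


def stepwise_variance(
    obs_a,
    pred_a,
    obs_b: pd.DataFrame,
    iterations: int = 100,
    train_frac: float = 0.8,
    seed: int = 0,
    gene_a: str = "A",
    keep_iterations: bool = False,
) -> StepwiseSummary:
    """Repeated stepwise regression over random train/test splits.

    Per iteration the partner-gene order is randomised, the data split into
    ``train_frac`` training and the rest test, and a bidirectional
    AIC-stepwise search run between the cis-only lower model and the full
    main + interaction upper model.  Test-fold pseudo-R^2 is computed for
    the selected model and for the same model stripped of its interaction
    terms; their difference is the interaction-only share.

    Requires at least two partner genes (a single partner is handled by the
    fixed nested comparison in :func:`pseudo_r2_decomposition` instead).
    """
    obs_a = np.asarray(obs_a, dtype=float)
    pred_a = np.asarray(pred_a, dtype=float)
    if obs_b.shape[1] < 2:
        raise ValueError("stepwise variance needs >= 2 partner genes")
    n = len(obs_a)
    genes = list(obs_b.columns)
    rng = np.random.default_rng(seed)

    rows = []
    n_skipped = 0
    sel_counts: dict[str, int] = {}
    for it in range(iterations):
        order = list(rng.permutation(genes))
        idx = rng.permutation(n)
        n_train = int(round(train_frac * n))
        tr, te = idx[:n_train], idx[n_train:]
        max_params = 2 + 2 * len(genes)
        if len(tr) <= max_params or len(te) < 3:
            n_skipped += 1
            continue
        y_tr, y_te = obs_a[tr], obs_a[te]
        pa_tr, pa_te = pred_a[tr], pred_a[te]
        B_tr, B_te = obs_b.iloc[tr], obs_b.iloc[te]

        terms = _stepwise(y_tr, pa_tr, B_tr, order)
        for t in terms:
            sel_counts[t] = sel_counts.get(t, 0) + 1
        main_terms = [t for t in terms if t.startswith("b:")]

        X_tr_full = _design(pa_tr, B_tr, terms)
        beta_full, rss_tr_full, rank_full = ols_fit(X_tr_full, y_tr)
        X_tr_cis = _design(pa_tr, B_tr, [])
        _, rss_tr_cis, _ = ols_fit(X_tr_cis, y_tr)
        beta_main, _, _ = ols_fit(_design(pa_tr, B_tr, main_terms), y_tr)

        tss_te = float(np.sum((y_te - y_te.mean()) ** 2))
        rss_te_full = float(np.sum((y_te - _design(pa_te, B_te, terms) @ beta_full) ** 2))
        rss_te_main = float(np.sum((y_te - _design(pa_te, B_te, main_terms) @ beta_main) ** 2))
        r2_te_full = 1.0 - rss_te_full / tss_te if tss_te > 0 else 0.0
        r2_te_main = 1.0 - rss_te_main / tss_te if tss_te > 0 else 0.0

        rows.append(
            {
                "iteration": it,
                "n_terms": len(terms),
                "terms": ";".join(sorted(terms)),
                "aic": _aic(rss_tr_full, len(tr), rank_full),
                "deviance_train": rss_tr_full,
                "r2_cis_train": pseudo_r2(rss_tr_cis, y_tr),
                "r2_full_train": pseudo_r2(rss_tr_full, y_tr),
                "r2_full_test": r2_te_full,
                "r2_main_test": r2_te_main,
                "r2_interaction_test": r2_te_full - r2_te_main,
            }
        )

    log = pd.DataFrame(rows)
    n_done = len(log)
    if n_done == 0:
        raise ValueError("all stepwise iterations were skipped (training set too small)")
    return StepwiseSummary(
        gene_a=gene_a,
        n_iterations=n_done,
        n_skipped=n_skipped,
        r2_cis_train_mean=float(log["r2_cis_train"].mean()),
        r2_full_train_mean=float(log["r2_full_train"].mean()),
        r2_full_test_mean=float(log["r2_full_test"].mean()),
        r2_full_test_median=float(log["r2_full_test"].median()),
        r2_full_test_sd=float(log["r2_full_test"].std()),
        r2_main_test_mean=float(log["r2_main_test"].mean()),
        r2_interaction_test_mean=float(log["r2_interaction_test"].mean()),
        r2_interaction_test_median=float(log["r2_interaction_test"].median()),
        r2_interaction_test_sd=float(log["r2_interaction_test"].std()),
        selection_freq={t: c / n_done for t, c in sorted(sel_counts.items())},
        iterations=log if keep_iterations else None,
    )
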