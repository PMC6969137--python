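"""Small shared least-squares helpers used by the association modules."""

from __future__ import annotations

import numpy as np
from scipy import stats


def ols_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, int]:
    """Least-squares fit; returns (coefficients, RSS, rank)."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid), int(rank)


def nested_f_test(
    X_full: np.ndarray, X_reduced: np.ndarray, y: np.ndarray
) -> tuple[float, float, float, float]:
    """ANOVA F-test of a full model against a nested reduced model.

    Returns ``(F, p, rss_full, rss_reduced)``.  Degrees of freedom come from
    the matrix ranks, so collinear columns do not inflate the test.
    """
    n = len(y)
    _, rss_f, rank_f = ols_fit(X_full, y)
    _, rss_r, rank_r = ols_fit(X_reduced, y)
    df1 = rank_f - rank_r
    df2 = n - rank_f
    if df1 <= 0 or df2 <= 0:
        return np.nan, np.nan, rss_f, rss_r
    num = max(rss_r - rss_f, 0.0) / df1
    den = rss_f / df2
    if den == 0.0:
        return np.inf, 0.0, rss_f, rss_r
    F = num / den
    return float(F), float(stats.f.sf(F, df1, df2)), rss_f, rss_r


def pseudo_r2(rss: float, y: np.ndarray) -> float:
    """(null deviance - residual deviance) / null deviance for Gaussian fits."""
    tss = float(np.sum((y - np.mean(y)) ** 2))
    if tss == 0.0:
        return 0.0
    return 1.0 - rss / tss
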