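"""Gene-set enrichment of interacting partners and resampled score bands.

Two procedures: an upper-tail hypergeometric test of interacting partner
genes against the tested background, and a resampling band for per-gene
numeric scores (e.g., promoter binding levels) — the foreground median is
compared with a 95% interval of medians from repeated same-size random
draws out of the background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .veqtl import bh_fdr

__all__ = ["hypergeometric_enrichment", "resampled_background_band", "BackgroundBand"]


def hypergeometric_enrichment(
    foreground, background, sets: dict[str, set | list]
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``foreground`` in each gene set.

    Parameters
    ----------
    foreground
        Genes of interest (e.g., interacting partner genes).  Must be a
        subset of ``background``.
    background
        The tested universe (all genes the scan could have picked).
    sets
        Mapping set name -> member genes; members outside the background
        are ignored.

    Returns a table (set, set_size, overlap, p, fdr), BH-adjusted across sets.
    """
    fg = set(foreground)
    bg = set(background)
    stray = fg - bg
    if stray:
        raise ValueError(f"foreground gene(s) absent from background: {sorted(stray)[:5]}")
    M, N = len(bg), len(fg)
    rows = []
    for name, members in sets.items():
        in_bg = set(members) & bg
        k = len(fg & in_bg)
        n = len(in_bg)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        rows.append({"set": name, "set_size": n, "overlap": k, "p": min(p, 1.0)})
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = bh_fdr(table["p"].to_numpy())
    return table


@dataclass
class BackgroundBand:
    foreground_median: float
    background_median: float
    band_low: float
    band_high: float
    outside: bool
    n_resamples: int


def resampled_background_band(
    scores: pd.DataFrame,
    n_resamples: int = 100,
    seed: int = 0,
    score_col: str = "score",
    label_col: str = "label",
) -> BackgroundBand:
    """Compare a foreground score median against a resampled background band.

    ``scores`` has one row per gene with a numeric ``score`` column and a
    ``label`` column equal to ``"foreground"`` or ``"background"``.  The
    band is the 2.5th–97.5th percentile of medians across ``n_resamples``
    same-size random draws (without replacement) from the background.
    """
    if n_resamples < 2:
        raise ValueError("n_resamples must be >= 2")
    fg = scores.loc[scores[label_col] == "foreground", score_col].to_numpy(dtype=float)
    bg = scores.loc[scores[label_col] == "background", score_col].to_numpy(dtype=float)
    if len(fg) == 0:
        raise ValueError("empty foreground")
    if len(bg) < len(fg):
        raise ValueError("background must be at least as large as the foreground")
    rng = np.random.default_rng(seed)
    medians = np.array(
        [np.median(rng.choice(bg, size=len(fg), replace=False)) for _ in range(n_resamples)]
    )
    low, high = np.percentile(medians, [2.5, 97.5])
    fg_med = float(np.median(fg))
    return BackgroundBand(
        foreground_median=fg_med,
        background_median=float(np.median(bg)),
        band_low=float(low),
        band_high=float(high),
        outside=bool(fg_med < low or fg_med > high),
        n_resamples=n_resamples,
    )
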