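"""In-memory containers shared across pipeline stages.

Expression matrices are plain :class:`pandas.DataFrame` objects with
individuals as the row index and probes as columns; gene annotation and
covariate tables are also DataFrames.  Genotypes get a thin dataclass so
that the dosage array and the SNP coordinate table travel together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele-dosage matrix with SNP coordinates.

    Parameters
    ----------
    dosages
        Array of shape ``(n_individuals, n_snps)`` with allele dosages in
        ``[0, 2]`` (hard calls or imputed expectations).
    snps
        DataFrame indexed by SNP id with columns ``chrom``, ``pos`` and
        optionally ``ref``, ``alt``, ``maf``.
    individuals
        Individual identifiers, one per dosage row.
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    individuals: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D individuals x SNPs array")
        if self.dosages.shape[1] != len(self.snps):
            raise ValueError(
                f"{self.dosages.shape[1]} dosage columns but {len(self.snps)} SNP records"
            )
        if self.dosages.shape[0] != len(self.individuals):
            raise ValueError(
                f"{self.dosages.shape[0]} dosage rows but {len(self.individuals)} individuals"
            )
        for col in ("chrom", "pos"):
            if col not in self.snps.columns:
                raise ValueError(f"snps table lacks required column {col!r}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps.index)

    def restrict(self, snp_ids) -> "GenotypeMatrix":
        """Return a new matrix containing only ``snp_ids`` (order preserved)."""
        idx = self.snps.index.get_indexer(list(snp_ids))
        if (idx < 0).any():
            missing = [s for s, i in zip(snp_ids, idx) if i < 0]
            raise KeyError(f"SNPs absent from genotype matrix: {missing[:5]}")
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            snps=self.snps.iloc[idx],
            individuals=list(self.individuals),
        )

    def dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.individuals, columns=self.snps.index)


@dataclass
class CohortData:
    """One cohort's genotypes, expression, annotation and covariates.

    ``expression`` is individuals x probes; ``annotation`` has one row per
    probe with columns ``probe``, ``gene``, ``chrom``, ``tss``, ``tes``,
    ``strand``; ``covariates`` has one row per individual (numeric columns
    are fixed effects, string/categorical columns are batch factors).
    """

    name: str
    genotypes: GenotypeMatrix
    expression: pd.DataFrame
    annotation: pd.DataFrame
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        inds = list(self.expression.index)
        if list(self.genotypes.individuals) != inds:
            raise ValueError(f"cohort {self.name}: genotype/expression individuals differ")
        if list(self.covariates.index) != inds:
            raise ValueError(f"cohort {self.name}: covariate/expression individuals differ")
        missing = set(self.expression.columns) - set(self.annotation["probe"])
        if missing:
            raise ValueError(
                f"cohort {self.name}: probes without annotation: {sorted(missing)[:5]}"
            )

    @property
    def n_individuals(self) -> int:
        return self.expression.shape[0]

    @property
    def probes(self) -> list[str]:
        return list(self.expression.columns)
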