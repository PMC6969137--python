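"""Plain-text readers/writers for the pipeline's exchange formats.

Genotypes travel as PLINK-style dosage text (one SNP per row: id, chrom,
pos, ref/alt alleles, then one dosage per individual); expression,
annotation, covariate and result tables as TSV; gene sets as GMT; ground
truth and manifests as JSON.  Floats are written with a fixed format so a
fixed-seed run is byte-reproducible.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import GenotypeMatrix

FLOAT_FMT = "%.10g"


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression(expr: pd.DataFrame, path) -> None:
    """Expression TSV with probes as rows and individuals as columns."""
    expr.T.to_csv(path, sep="\t", index_label="probe", float_format=FLOAT_FMT)


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe").T


def write_dosage(geno: GenotypeMatrix, path) -> None:
    snps = geno.snps
    with open(path, "w") as fh:
        fh.write("snp\tchrom\tpos\tref\talt\t" + "\t".join(geno.individuals) + "\n")
        for j, (sid, row) in enumerate(snps.iterrows()):
            dos = "\t".join(FLOAT_FMT % d for d in geno.dosages[:, j])
            fh.write(
                f"{sid}\t{row['chrom']}\t{row['pos']}\t{row.get('ref', 'A')}"
                f"\t{row.get('alt', 'B')}\t{dos}\n"
            )


def read_dosage(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["snp", "chrom", "pos", "ref", "alt"]
    individuals = [c for c in df.columns if c not in meta_cols]
    snps = df[meta_cols].set_index("snp")
    dosages = df[individuals].to_numpy(dtype=float).T
    return GenotypeMatrix(dosages=dosages, snps=snps, individuals=individuals)


def write_covariates(cov: pd.DataFrame, path) -> None:
    cov.to_csv(path, sep="\t", index_label="individual", float_format=FLOAT_FMT)


def read_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="individual")


def read_gmt(path) -> dict[str, set]:
    """GMT gene sets: name <tab> description <tab> member genes."""
    sets: dict[str, set] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(sets: dict[str, set | list], path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, name] + sorted(members)) + "\n")


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_model_store(models: dict, weights_path, meta_path) -> None:
    """Model store: TSV of (gene, snp, weight) plus JSON metadata."""
    import json

    rows = []
    meta = {}
    for gene, m in sorted(models.items()):
        for s, w, mu, sd in zip(m.snp_ids, m.weights, m.snp_means, m.snp_sds):
            if w != 0.0:
                rows.append(
                    {"gene": gene, "snp": s, "weight": w, "snp_mean": mu, "snp_sd": sd}
                )
        meta[gene] = {
            "intercept": m.intercept,
            "alpha": None if np.isnan(m.alpha) else m.alpha,
            "cv_r2": m.cv_r2,
            "cv_p": m.cv_p,
            "cv_fdr": None if np.isnan(m.cv_fdr) else m.cv_fdr,
            "trainable": m.trainable,
            "transfer_r2": m.transfer_r2,
        }
    write_table(pd.DataFrame(rows, columns=["gene", "snp", "weight", "snp_mean", "snp_sd"]),
                weights_path)
    Path(meta_path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_model_store(weights_path, meta_path) -> dict:
    """Rebuild prediction-capable cis models from the on-disk store.

    Only nonzero-weight SNPs are stored, which is all prediction needs.
    """
    import json

    from .cis import CisModel

    weights = pd.read_csv(weights_path, sep="\t")
    meta = json.loads(Path(meta_path).read_text())
    models: dict[str, CisModel] = {}
    for gene, m in meta.items():
        rows = weights[weights["gene"] == gene]
        models[gene] = CisModel(
            gene=gene,
            snp_ids=list(rows["snp"]),
            weights=rows["weight"].to_numpy(dtype=float),
            intercept=float(m["intercept"]),
            snp_means=rows["snp_mean"].to_numpy(dtype=float),
            snp_sds=rows["snp_sd"].to_numpy(dtype=float),
            cv_r2=float(m["cv_r2"]),
            cv_p=float(m["cv_p"]),
            alpha=np.nan if m["alpha"] is None else float(m["alpha"]),
            trainable=bool(m["trainable"]),
            cv_fdr=np.nan if m.get("cv_fdr") is None else float(m["cv_fdr"]),
            transfer_r2=dict(m.get("transfer_r2", {})),
        )
    return models
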