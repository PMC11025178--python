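"""Readers and writers for the pipeline's plain-text formats.

Genotypes travel as VCF (GT field) or as a TSV dosage matrix (variants in
rows, samples in columns, ``NA`` for missing); cohorts, summary statistics,
incidence tables and PRS models are TSV with fixed column schemas.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (GenotypeMatrix, PRSModel, SurvivalCohort,
                         SUMSTATS_COLUMNS, validate_sumstats)
from .exceptions import ValidationError

GT_CODES = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_dosage_tsv(g: GenotypeMatrix, path) -> None:
    df = g.variants.copy()
    dmat = pd.DataFrame(g.dosages.T, columns=g.samples)
    pd.concat([df.reset_index(drop=True), dmat], axis=1).to_csv(
        path, sep="\t", index=False, na_rep="NA")


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    meta_cols = ["variant_id", "chr", "pos", "ea", "oa"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ValidationError(f"dosage TSV lacks columns {missing}")
    samples = [c for c in df.columns if c not in meta_cols]
    dosages = df[samples].to_numpy(dtype=float).T
    return GenotypeMatrix(dosages, df[meta_cols], samples)


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write hard-call genotypes as a minimal VCF 4.2 (GT only).

    The effect allele is written as ALT so that the ALT-allele dosage in
    the file equals the matrix dosage.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(g.variants["chr"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        order = np.lexsort((g.variants["pos"].to_numpy(),
                            g.variants["chr"].to_numpy()))
        for j in order:
            row = g.variants.iloc[j]
            gts = [GT_CODES.get(d, "./.") if not np.isnan(d) else "./."
                   for d in g.dosages[:, j]]
            fh.write(f"{row['chr']}\t{row['pos']}\t{row['variant_id']}\t"
                     f"{row['oa']}\t{row['ea']}\t.\t.\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a GT-only VCF back into a dosage matrix (ALT-allele dosage)."""
    try:
        from cyvcf2 import VCF
    except ImportError:  # pragma: no cover - cyvcf2 is a std dependency
        return _read_vcf_text(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosage_cols = [], []
    for rec in vcf:
        rows.append({"variant_id": rec.ID, "chr": _chrom_int(rec.CHROM),
                     "pos": rec.POS, "ea": rec.ALT[0], "oa": rec.REF})
        gts = np.asarray(rec.gt_types, dtype=float)  # 0,1,3 =hom/het/homalt; 2=unknown
        dos = np.where(gts == 0, 0.0,
                       np.where(gts == 1, 1.0,
                                np.where(gts == 3, 2.0, np.nan)))
        dosage_cols.append(dos)
    return GenotypeMatrix(np.array(dosage_cols).T, pd.DataFrame(rows), samples)


def _chrom_int(c):
    try:
        return int(str(c).removeprefix("chr"))
    except ValueError:
        return str(c)


def _read_vcf_text(path) -> GenotypeMatrix:
    rows, dosage_cols, samples = [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = parts[9:]
                continue
            chrom, pos, vid, ref, alt = parts[:5]
            rows.append({"variant_id": vid, "chr": _chrom_int(chrom),
                         "pos": int(pos), "ea": alt, "oa": ref})
            dos = []
            for gt in parts[9:]:
                alleles = gt.split(":")[0].replace("|", "/").split("/")
                if "." in alleles:
                    dos.append(np.nan)
                else:
                    dos.append(float(sum(int(a) for a in alleles)))
            dosage_cols.append(dos)
    return GenotypeMatrix(np.array(dosage_cols, dtype=float).T,
                          pd.DataFrame(rows), samples)


def write_cohort(c: SurvivalCohort, path) -> None:
    c.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_cohort(path, covariates=None, label="General") -> SurvivalCohort:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if covariates is None:
        base = {"sample_id", "entry_age", "exit_age", "event", "fh"}
        covariates = [c for c in df.columns if c not in base]
    return SurvivalCohort(df, covariates=list(covariates), label=label)


def write_sumstats(df: pd.DataFrame, path) -> None:
    validate_sumstats(df)[SUMSTATS_COLUMNS].to_csv(
        path, sep="\t", index=False, na_rep="NA")


def read_sumstats(path) -> pd.DataFrame:
    return validate_sumstats(pd.read_csv(path, sep="\t", na_values=["NA"]))


def write_prs_model(model: PRSModel, path) -> None:
    model.entries.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_prs_model(path, name=None) -> PRSModel:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return PRSModel(df, name=name or Path(path).stem)


def read_incidence(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"age_start", "age_end", "rate_per_100k"}
    if not need.issubset(df.columns):
        raise ValidationError(f"incidence table needs columns {sorted(need)}")
    return df


def write_incidence(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
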