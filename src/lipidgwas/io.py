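"""Readers and writers for the pipeline's file formats.

Phenotype/covariate/endpoint tables are tab-delimited with a sample-id first
column and NA for missing.  Genotypes travel as VCF with a per-sample DS
(dosage) FORMAT field, written with pysam and read with cyvcf2.  Summary
statistics use GWAS-catalog-style column names.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_table",
    "write_table",
    "write_vcf",
    "read_vcf",
    "write_sumstats",
    "read_sumstats",
]

SUMSTATS_COLUMNS = {
    "chrom": "chromosome",
    "pos": "base_pair_location",
    "id": "variant_id",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "effect_allele_frequency",
    "beta": "beta",
    "se": "standard_error",
    "p": "p_value",
    "n": "n",
    "info": "info",
}


def read_table(path: str | Path) -> pd.DataFrame:
    """Tab-delimited table with sample ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")


def write_vcf(path: str | Path, dosages: np.ndarray,
              variants: pd.DataFrame, sample_ids: list[str]) -> None:
    """Write dosages as an uncompressed VCF with a DS FORMAT field."""
    import pysam

    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "DS"), ("Number", "1"),
                                     ("Type", "Float"),
                                     ("Description", "Imputed dosage")])
    header.add_meta("INFO", items=[("ID", "INFO"), ("Number", "1"),
                                   ("Type", "Float"),
                                   ("Description", "Imputation quality")])
    for chrom in pd.unique(variants["chrom"]):
        header.contigs.add(str(chrom))
    for s in sample_ids:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, row in enumerate(variants.itertuples()):
            rec = vcf.new_record(
                contig=str(row.chrom), start=int(row.pos) - 1,
                stop=int(row.pos), alleles=(row.ref, row.alt), id=row.id,
            )
            rec.info["INFO"] = float(row.info)
            for i, s in enumerate(sample_ids):
                rec.samples[s]["DS"] = float(dosages[i, j])
            vcf.write(rec)


def read_vcf(path: str | Path) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Read a dosage VCF; returns (dosages, variant table, sample ids)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, rows = [], []
    for rec in vcf:
        ds = rec.format("DS")
        cols.append(np.asarray(ds, float).ravel())
        freq = float(np.mean(cols[-1]) / 2.0)
        rows.append({
            "chrom": rec.CHROM,
            "pos": rec.POS,
            "id": rec.ID or f"{rec.CHROM}_{rec.POS}",
            "ref": rec.REF,
            "alt": rec.ALT[0] if rec.ALT else ".",
            "maf": min(freq, 1.0 - freq),
            "info": float(rec.INFO.get("INFO", 1.0)),
        })
    vcf.close()
    dosages = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return dosages, pd.DataFrame(rows), samples


def write_sumstats(records: pd.DataFrame, path: str | Path) -> None:
    out = records.rename(columns=SUMSTATS_COLUMNS)
    out.to_csv(path, sep="\t", index=False)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    inv = {v: k for k, v in SUMSTATS_COLUMNS.items()}
    return pd.read_csv(path, sep="\t").rename(columns=inv)
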