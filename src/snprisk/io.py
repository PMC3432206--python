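"""Readers and writers for PLINK text formats and the internal dosage TSV.

Supported: .ped/.map pairs, the additive .raw dump (counted allele encoded
in the header as ``snpid_X``), and a tab-separated dosage matrix with a
header row of SNP ids plus a phenotype column.  Missing genotypes are a
declared limitation: a ``0 0`` pair or an NA dosage raises with the line
number.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .datatypes import GenotypeDataset, SNP_COLUMNS


class PlinkFormatError(ValueError):
    pass


# ----------------------------------------------------------------------
# .ped / .map
# ----------------------------------------------------------------------

def write_plink_text(dataset: GenotypeDataset, prefix: str) -> None:
    """Write ``prefix.ped`` and ``prefix.map``.

    Phenotype is coded 1 = control, 2 = case (-9 when absent); each dosage g
    becomes g copies of the counted allele and 2 - g of the other.
    """
    prefix = str(prefix)
    snps = dataset.snps
    with open(prefix + ".map", "w") as fh:
        for _, row in snps.iterrows():
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.position}\n")
    counted = snps["counted_allele"].to_numpy()
    other = np.where(
        snps["allele_b"].to_numpy() == counted,
        snps["allele_a"].to_numpy(),
        snps["allele_b"].to_numpy(),
    )
    y = dataset.phenotype
    with open(prefix + ".ped", "w") as fh:
        for i in range(dataset.n_subjects):
            pheno = -9 if y is None else int(y[i]) + 1
            fields = [str(dataset.subject_ids[i])] * 2 + ["0", "0", "1", str(pheno)]
            g = dataset.genotypes[i]
            for j in range(dataset.n_snps):
                if g[j] == 2:
                    fields += [counted[j], counted[j]]
                elif g[j] == 1:
                    fields += [other[j], counted[j]]
                else:
                    fields += [other[j], other[j]]
            fh.write(" ".join(fields) + "\n")


def read_plink_text(
    prefix: str, counted_alleles: Optional[Mapping[str, str]] = None
) -> GenotypeDataset:
    """Read a ``.ped``/``.map`` pair into a dosage matrix.

    The counted allele per SNP is taken from ``counted_alleles`` when given,
    otherwise the minor allele observed in the file (ties broken
    alphabetically).  Missing genotypes (allele code ``0``) and
    non-biallelic SNPs raise PlinkFormatError.
    """
    prefix = str(prefix)
    map_rows = []
    with open(prefix + ".map") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 4:
                raise PlinkFormatError(f"{prefix}.map line {lineno}: expected 4 fields")
            map_rows.append((parts[0], parts[1], int(parts[3])))
    n_snps = len(map_rows)
    subject_ids, phenos, allele_rows = [], [], []
    with open(prefix + ".ped") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 6 + 2 * n_snps:
                raise PlinkFormatError(
                    f"{prefix}.ped line {lineno}: expected {6 + 2 * n_snps} fields, "
                    f"got {len(parts)}"
                )
            alleles = parts[6:]
            if "0" in alleles:
                raise PlinkFormatError(
                    f"{prefix}.ped line {lineno}: missing genotype ('0' allele) "
                    "is not supported"
                )
            subject_ids.append(parts[1])
            phenos.append(parts[5])
            allele_rows.append(alleles)
    alleles = np.array(allele_rows, dtype=object).reshape(len(subject_ids), n_snps, 2)
    genotypes = np.zeros((len(subject_ids), n_snps), dtype=np.int8)
    snp_meta = []
    for j, (chrom, snp_id, position) in enumerate(map_rows):
        col = alleles[:, j, :]
        observed = sorted(set(col.ravel().tolist()))
        if len(observed) > 2:
            raise PlinkFormatError(f"SNP {snp_id} is not biallelic: {observed}")
        if counted_alleles is not None and snp_id in counted_alleles:
            counted = counted_alleles[snp_id]
        else:
            freqs = {a: (col == a).sum() for a in observed}
            counted = min(observed, key=lambda a: (freqs[a], a))
        others = [a for a in observed if a != counted] or [counted]
        genotypes[:, j] = (col == counted).sum(axis=1)
        snp_meta.append(
            {
                "snp_id": snp_id,
                "chrom": chrom,
                "position": position,
                "allele_a": others[0],
                "allele_b": counted,
                "counted_allele": counted,
            }
        )
    pheno_arr = None
    codes = set(phenos)
    if codes <= {"1", "2"}:
        pheno_arr = np.array([int(p) - 1 for p in phenos], dtype=np.int8)
    return GenotypeDataset(
        genotypes=genotypes,
        snps=pd.DataFrame(snp_meta)[SNP_COLUMNS],
        phenotype=pheno_arr,
        subject_ids=np.array(subject_ids, dtype=object),
    )


# ----------------------------------------------------------------------
# additive .raw dump
# ----------------------------------------------------------------------

def write_raw(dataset: GenotypeDataset, path: str) -> None:
    """Write a PLINK-style additive dump; header column ``snpid_X`` records
    the counted allele X."""
    cols = [
        f"{s}_{a}"
        for s, a in zip(dataset.snps["snp_id"], dataset.snps["counted_allele"])
    ]
    y = dataset.phenotype
    header = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"] + cols
    with open(path, "w") as fh:
        fh.write(" ".join(header) + "\n")
        for i in range(dataset.n_subjects):
            pheno = -9 if y is None else int(y[i]) + 1
            sid = str(dataset.subject_ids[i])
            row = [sid, sid, "0", "0", "1", str(pheno)]
            row += [str(int(v)) for v in dataset.genotypes[i]]
            fh.write(" ".join(row) + "\n")


def read_raw(path: str) -> GenotypeDataset:
    df = pd.read_csv(path, sep=r"\s+")
    snp_cols = [c for c in df.columns if c not in
                {"FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"}]
    geno = df[snp_cols]
    if geno.isna().any().any():
        bad = int(np.argwhere(geno.isna().to_numpy())[0][0]) + 2
        raise PlinkFormatError(f"{path} line {bad}: missing dosage is not supported")
    snp_meta = []
    for c in snp_cols:
        snp_id, _, allele = c.rpartition("_")
        snp_meta.append(
            {
                "snp_id": snp_id,
                "chrom": 0,
                "position": 0,
                "allele_a": "N",
                "allele_b": allele,
                "counted_allele": allele,
            }
        )
    pheno = df["PHENOTYPE"].to_numpy()
    pheno_arr = (pheno - 1).astype(np.int8) if set(pheno) <= {1, 2} else None
    return GenotypeDataset(
        genotypes=geno.to_numpy().astype(np.int8),
        snps=pd.DataFrame(snp_meta)[SNP_COLUMNS],
        phenotype=pheno_arr,
        subject_ids=df["IID"].to_numpy(dtype=object),
    )


# ----------------------------------------------------------------------
# internal dosage TSV fixture format
# ----------------------------------------------------------------------

def write_dosage_tsv(dataset: GenotypeDataset, path: str) -> None:
    """Tab-separated dosage matrix: SNP-id header + ``phenotype`` column."""
    df = pd.DataFrame(dataset.genotypes, columns=dataset.snp_ids)
    if dataset.phenotype is not None:
        df["phenotype"] = dataset.phenotype
    df.insert(0, "subject_id", dataset.subject_ids)
    df.to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path: str) -> GenotypeDataset:
    df = pd.read_csv(path, sep="\t")
    subject_ids = df.pop("subject_id").to_numpy(dtype=object)
    pheno = df.pop("phenotype").to_numpy() if "phenotype" in df.columns else None
    snp_ids = list(df.columns)
    snps = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": 0,
            "position": np.arange(len(snp_ids)),
            "allele_a": "A",
            "allele_b": "B",
            "counted_allele": "B",
        }
    )[SNP_COLUMNS]
    return GenotypeDataset(
        genotypes=df.to_numpy().astype(np.int8),
        snps=snps,
        phenotype=pheno,
        subject_ids=subject_ids,
    )
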