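"""Readers and writers for PLINK ped/map, VCF and the pipeline's TSV tables.

PLINK text files are parsed directly (the format is two allele
characters per SNP with ``0 0`` for missing); VCF input goes through
cyvcf2 and uses only the GT field of biallelic records.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, make_marker_map, sort_marker_map

MISSING_ALLELE = "0"


def read_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", header=None,
                     names=["chromosome", "snp_id", "cm", "position_bp"],
                     dtype={"chromosome": str, "snp_id": str})
    return make_marker_map(df["snp_id"], df["chromosome"], df["position_bp"])


def read_plink(prefix):
    """Read a PLINK .ped/.map pair into (GenotypeMatrix, marker_map).

    Dosage counts copies of allele_b (the first-seen allele per SNP is
    allele_a).  The map is sorted by (chromosome, position) and genotype
    columns are reordered to match.
    """
    prefix = str(prefix)
    raw_map = pd.read_csv(prefix + ".map", sep=r"\s+", header=None,
                          names=["chromosome", "snp_id", "cm", "position_bp"],
                          dtype={"chromosome": str, "snp_id": str})
    m = len(raw_map)
    ids, rows = [], []
    with open(prefix + ".ped") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            ids.append(parts[1])
            alleles = parts[6:]
            if len(alleles) != 2 * m:
                raise ValueError(
                    f".ped row for {parts[1]} has {len(alleles)} allele fields, expected {2*m}"
                )
            rows.append(alleles)
    allele_a = [None] * m
    allele_b = [None] * m
    dosages = np.full((len(ids), m), np.nan)
    for j in range(m):
        for i, row in enumerate(rows):
            a1, a2 = row[2 * j], row[2 * j + 1]
            if a1 == MISSING_ALLELE or a2 == MISSING_ALLELE:
                continue
            for al in (a1, a2):
                if allele_a[j] is None:
                    allele_a[j] = al
                elif allele_b[j] is None and al != allele_a[j]:
                    allele_b[j] = al
            d = 0
            for al in (a1, a2):
                if allele_b[j] is not None and al == allele_b[j]:
                    d += 1
            dosages[i, j] = d
    allele_a = [a if a is not None else "A" for a in allele_a]
    allele_b = [b if b is not None else "B" for b in allele_b]
    marker_map = make_marker_map(raw_map["snp_id"], raw_map["chromosome"],
                                 raw_map["position_bp"], allele_a, allele_b)
    order = [list(raw_map["snp_id"]).index(s) for s in marker_map["snp_id"]]
    g = GenotypeMatrix(
        ids=np.array(ids, dtype=object),
        snp_ids=marker_map["snp_id"].to_numpy(),
        dosages=dosages[:, order],
    )
    return g, marker_map


def write_plink(g: GenotypeMatrix, marker_map: pd.DataFrame, prefix):
    """Write a PLINK .ped/.map pair (dosages rounded to integer calls)."""
    prefix = str(prefix)
    os.makedirs(os.path.dirname(prefix) or ".", exist_ok=True)
    mm = marker_map.set_index("snp_id").loc[list(g.snp_ids)].reset_index()
    with open(prefix + ".map", "w") as fh:
        for _, r in mm.iterrows():
            fh.write(f"{r['chromosome']}\t{r['snp_id']}\t0\t{r['position_bp']}\n")
    aa = mm["allele_a"].to_numpy()
    bb = mm["allele_b"].to_numpy()
    with open(prefix + ".ped", "w") as fh:
        for i, ind in enumerate(g.ids):
            fields = ["FAM", str(ind), "0", "0", "0", "-9"]
            row = g.dosages[i]
            for j, d in enumerate(row):
                if np.isnan(d):
                    fields.extend([MISSING_ALLELE, MISSING_ALLELE])
                else:
                    d = int(round(d))
                    pair = {0: (aa[j], aa[j]), 1: (aa[j], bb[j]), 2: (bb[j], bb[j])}[d]
                    fields.extend(pair)
            fh.write(" ".join(fields) + "\n")


def read_vcf(path):
    """Read biallelic SNP genotypes (GT field) from a VCF via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = np.array(vcf.samples, dtype=object)
    snp_ids, chroms, positions, ref, alt, cols = [], [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        snp_ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        positions.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        gt = np.asarray(var.gt_types, dtype=float)  # 0 homref, 1 het, 2 unknown, 3 homalt
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        cols.append(dos)
    marker_map = make_marker_map(snp_ids, chroms, positions, ref, alt)
    raw = np.column_stack(cols) if cols else np.empty((len(ids), 0))
    order = [snp_ids.index(s) for s in marker_map["snp_id"]]
    g = GenotypeMatrix(ids=ids, snp_ids=marker_map["snp_id"].to_numpy(),
                       dosages=raw[:, order])
    return g, marker_map


def write_vcf(g: GenotypeMatrix, marker_map: pd.DataFrame, path):
    """Write a minimal VCF (GT only) with integer-rounded genotypes."""
    mm = marker_map.set_index("snp_id").loc[list(g.snp_ids)].reset_index()
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(i) for i in g.ids) + "\n")
        for j, (_, r) in enumerate(mm.iterrows()):
            calls = []
            for d in g.dosages[:, j]:
                calls.append("./." if np.isnan(d) else gt_codes[int(round(d))])
            fh.write(
                f"{r['chromosome']}\t{r['position_bp']}\t{r['snp_id']}\t"
                f"{r['allele_a']}\t{r['allele_b']}\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_pheno(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "individual_id" not in df.columns or "debv" not in df.columns:
        raise ValueError("phenotype table needs columns individual_id and debv")
    df["individual_id"] = df["individual_id"].astype(str)
    return df


def write_tsv(df: pd.DataFrame, path):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
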