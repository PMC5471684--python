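"""Core in-memory containers shared across the pipeline.

The pipeline operates on a dense dosage matrix (individuals x SNPs, allele
counts 0/1/2 with NaN for missing calls) plus a physical marker map.  The
map is kept as a plain :class:`pandas.DataFrame` sorted by (chromosome,
position) so that window assignment follows physical map order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MAP_COLUMNS = ["snp_id", "chromosome", "position_bp", "allele_a", "allele_b"]


def make_marker_map(
    snp_ids,
    chromosomes,
    positions_bp,
    allele_a=None,
    allele_b=None,
) -> pd.DataFrame:
    """Assemble and validate a marker map, sorted by (chromosome, position).

    Chromosome labels sort numerically when they look like integers,
    lexically otherwise, mirroring PLINK map conventions.
    """
    n = len(snp_ids)
    df = pd.DataFrame(
        {
            "snp_id": np.asarray(snp_ids, dtype=object),
            "chromosome": np.asarray(chromosomes, dtype=object).astype(str),
            "position_bp": np.asarray(positions_bp, dtype=np.int64),
            "allele_a": np.asarray(allele_a, dtype=object) if allele_a is not None else ["A"] * n,
            "allele_b": np.asarray(allele_b, dtype=object) if allele_b is not None else ["B"] * n,
        }
    )
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValueError(f"duplicate snp_id in marker map: {dup!r}")
    if (df["position_bp"] < 0).any():
        raise ValueError("negative position_bp in marker map")
    df = sort_marker_map(df)
    return df


def _chrom_sort_key(chrom: pd.Series) -> pd.Series:
    as_num = pd.to_numeric(chrom, errors="coerce")
    if as_num.notna().all():
        return as_num
    return chrom.astype(str)


def sort_marker_map(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["_ck"] = _chrom_sort_key(df["chromosome"])
    df = df.sort_values(["_ck", "position_bp"], kind="mergesort").drop(columns="_ck")
    return df.reset_index(drop=True)


@dataclass
class GenotypeMatrix:
    """Dense individuals x SNPs dosage matrix.

    Parameters
    ----------
    ids
        Individual identifiers, one per row.
    snp_ids
        SNP identifiers, one per column, in marker-map order.
    dosages
        (n, m) float array of allele counts in {0, 1, 2}; NaN marks a
        missing call.  After imputation entries may be fractional
        (expected dosages).
    coding_center, coding_scale
        Linear recode descriptor: the covariate actually fed to the
        regression is ``(dosage - coding_center) * coding_scale``.  The
        default (0, 1) keeps raw 0/1/2 counts; (1, 10) reproduces the
        -10/0/10 coding used by GenSel-style software.
    """

    ids: np.ndarray
    snp_ids: np.ndarray
    dosages: np.ndarray
    coding_center: float = 0.0
    coding_scale: float = 1.0

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x SNPs)")
        if self.dosages.shape != (len(self.ids), len(self.snp_ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.ids)} ids x {len(self.snp_ids)} SNPs"
            )
        if self.coding_scale == 0:
            raise ValueError("coding_scale must be nonzero")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def coded(self) -> np.ndarray:
        """Covariate matrix under the configured linear recode."""
        return (self.dosages - self.coding_center) * self.coding_scale

    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosages).any())

    def individual_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def snp_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def subset(self, row_mask=None, col_mask=None) -> "GenotypeMatrix":
        rows = np.arange(self.n_individuals) if row_mask is None else np.flatnonzero(np.asarray(row_mask))
        if col_mask is None:
            cols = np.arange(self.n_snps)
        else:
            col_mask = np.asarray(col_mask)
            cols = np.flatnonzero(col_mask) if col_mask.dtype == bool else col_mask
        return replace(
            self,
            ids=self.ids[rows],
            snp_ids=self.snp_ids[cols],
            dosages=self.dosages[np.ix_(rows, cols)].copy(),
        )

    def select_snps(self, snp_ids) -> "GenotypeMatrix":
        """Column subset by SNP id, preserving the requested order."""
        index = {s: j for j, s in enumerate(self.snp_ids)}
        try:
            cols = np.array([index[s] for s in snp_ids], dtype=np.intp)
        except KeyError as err:
            raise KeyError(f"SNP {err.args[0]!r} not present in genotype matrix") from None
        return replace(
            self,
            snp_ids=np.asarray(list(snp_ids), dtype=object),
            dosages=self.dosages[:, cols].copy(),
        )
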