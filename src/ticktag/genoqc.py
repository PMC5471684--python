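"""Sample and SNP quality control with simple expected-dosage imputation.

Filters follow the screening protocol for medium-density bovine chip
data: individuals are dropped for call rate < 90%, heterozygosity more
than three SDs from the cohort mean, or near-perfect genotype
concordance (> 99.5%) with another individual; SNPs are dropped for call
rate < 98%, MAF < 3%, Hardy-Weinberg disequilibrium (1-df chi-square,
P < 1e-7), or redundancy with a same-position / > 98%-correlated SNP
(the highest-MAF member of each redundancy group is kept).  All "lower
than"/"higher than" thresholds are strict, as worded.

Sporadically missing genotypes that survive QC are filled with the
per-SNP expected dosage 2p (left fractional): post-QC missingness is at
most 2% per SNP, so mean imputation is adequate for the downstream
whole-genome regression.  A sex-misidentification check is a no-op here
(no sex chromosomes are modelled).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .containers import GenotypeMatrix

IND_CALL_RATE = 0.90
SNP_CALL_RATE = 0.98
MAF_MIN = 0.03
HWE_P_MIN = 1e-7
CONCORDANCE_MAX = 0.995
SNP_CORR_MAX = 0.98


@dataclass
class QcReport:
    """Removal bookkeeping: one primary reason per removed item."""

    removed_individuals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["individual_id", "reason"])
    )
    removed_snps: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp_id", "reason"])
    )
    filter_order: list = field(default_factory=list)

    def counts(self) -> dict:
        c = {}
        for _, row in self.removed_individuals.iterrows():
            c[row["reason"]] = c.get(row["reason"], 0) + 1
        for _, row in self.removed_snps.iterrows():
            c[row["reason"]] = c.get(row["reason"], 0) + 1
        return c

    def to_frame(self) -> pd.DataFrame:
        a = self.removed_individuals.rename(columns={"individual_id": "item"})
        a.insert(0, "kind", "individual")
        b = self.removed_snps.rename(columns={"snp_id": "item"})
        b.insert(0, "kind", "snp")
        return pd.concat([a, b], ignore_index=True)


def maf(column: np.ndarray) -> float:
    """Minor allele frequency of one dosage column (NaN-aware)."""
    column = np.asarray(column, dtype=float)
    ok = ~np.isnan(column)
    if not ok.any():
        return np.nan
    p = column[ok].mean() / 2.0
    return float(min(p, 1.0 - p))


def hwe_pvalue(column: np.ndarray) -> float:
    """1-df chi-square HWE test on genotype counts, no continuity correction."""
    column = np.asarray(column, dtype=float)
    ok = ~np.isnan(column)
    obs = np.array([(column[ok] == k).sum() for k in (0.0, 1.0, 2.0)], dtype=float)
    n = obs.sum()
    if n == 0:
        return np.nan
    p = (obs[1] + 2 * obs[2]) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0  # monomorphic: HWE trivially satisfied (fails MAF first)
    exp = np.array([q * q, 2 * p * q, p * p]) * n
    stat = float(((obs - exp) ** 2 / exp).sum())
    return float(chi2.sf(stat, df=1))


def _heterozygosity(dosages: np.ndarray) -> np.ndarray:
    called = ~np.isnan(dosages)
    het = (dosages == 1.0) & called
    with np.errstate(invalid="ignore"):
        return het.sum(axis=1) / called.sum(axis=1)


def _concordance_pairs(dosages: np.ndarray, threshold: float):
    """Return (i, j, fraction) for pairs with concordance > threshold over
    jointly non-missing SNPs (i < j).  Vectorized via indicator products."""
    called = ~np.isnan(dosages)
    joint = called.astype(np.float64) @ called.astype(np.float64).T
    same = np.zeros_like(joint)
    for v in (0.0, 1.0, 2.0):
        ind = ((dosages == v) & called).astype(np.float64)
        same += ind @ ind.T
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = same / joint
    frac[joint == 0] = 0.0
    ii, jj = np.nonzero(np.triu(frac > threshold, k=1))
    return [(int(i), int(j), float(frac[i, j])) for i, j in zip(ii, jj)]


def qc_individuals(g: GenotypeMatrix) -> tuple[GenotypeMatrix, QcReport]:
    """Drop low-call-rate, heterozygosity-outlier and duplicated individuals."""
    report = QcReport(filter_order=["call_rate", "heterozygosity", "collinearity"])
    removed = []

    cr = g.individual_call_rate()
    keep = cr >= IND_CALL_RATE
    for i in np.flatnonzero(~keep):
        removed.append((g.ids[i], "call_rate"))
    g = g.subset(row_mask=keep)

    het = _heterozygosity(g.dosages)
    mu, sd = float(np.nanmean(het)), float(np.nanstd(het))
    if sd > 0:
        dev = np.abs(het - mu)
        keep = dev <= 3.0 * sd
        for i in np.flatnonzero(~keep):
            removed.append((g.ids[i], "heterozygosity"))
        g = g.subset(row_mask=keep)

    cr = g.individual_call_rate()
    drop = set()
    for i, j, _ in _concordance_pairs(g.dosages, CONCORDANCE_MAX):
        if i in drop or j in drop:
            continue
        # keep the member with higher call rate; tie -> keep the first
        loser = j if cr[j] <= cr[i] else i
        drop.add(loser)
    keep = np.ones(g.n_individuals, dtype=bool)
    for i in sorted(drop):
        removed.append((g.ids[i], "collinearity"))
        keep[i] = False
    g = g.subset(row_mask=keep)

    if g.n_individuals < 2:
        raise ValueError("fewer than 2 individuals remain after sample QC")
    report.removed_individuals = pd.DataFrame(removed, columns=["individual_id", "reason"])
    return g, report


def _redundancy_groups(dosages, chromosomes, positions, candidates):
    """Transitive closure of same-position or >0.98-correlated SNP pairs."""
    m = len(candidates)
    # correlation on mean-filled, centered columns
    sub = dosages[:, candidates].astype(float)
    col_mean = np.nanmean(sub, axis=0)
    filled = np.where(np.isnan(sub), col_mean, sub)
    centered = filled - filled.mean(axis=0)
    sd = centered.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    corr = (centered / sd_safe).T @ (centered / sd_safe) / dosages.shape[0]
    corr[(sd == 0)[:, None] | (sd == 0)[None, :]] = 0.0

    parent = list(range(m))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    pos = positions[candidates]
    chrom = chromosomes[candidates]
    same_pos = (pos[:, None] == pos[None, :]) & (chrom[:, None] == chrom[None, :])
    offending = (np.abs(corr) > SNP_CORR_MAX) | same_pos
    for a, b in zip(*np.nonzero(np.triu(offending, k=1))):
        union(int(a), int(b))
    groups = {}
    for k in range(m):
        groups.setdefault(find(k), []).append(k)
    return [grp for grp in groups.values() if len(grp) > 1]


def qc_snps(g: GenotypeMatrix, marker_map: pd.DataFrame):
    """Drop low-call-rate, rare, HWE-violating and redundant SNPs.

    Assumes individuals have already been QCed.  Returns the filtered
    genotypes, the matching marker map and a QcReport.
    """
    if list(marker_map["snp_id"]) != list(g.snp_ids):
        raise ValueError("marker map and genotype matrix disagree on SNP order")
    report = QcReport(filter_order=["call_rate", "maf", "hwe", "redundancy"])
    removed = []
    m = g.n_snps
    reason = np.array([""] * m, dtype=object)

    cr = g.snp_call_rate()
    reason[cr < SNP_CALL_RATE] = "call_rate"

    mafs = np.array([maf(g.dosages[:, j]) for j in range(m)])
    sel = (reason == "") & (mafs < MAF_MIN)
    reason[sel] = "maf"

    for j in np.flatnonzero(reason == ""):
        if hwe_pvalue(g.dosages[:, j]) < HWE_P_MIN:
            reason[j] = "hwe"

    survivors = np.flatnonzero(reason == "")
    positions = marker_map["position_bp"].to_numpy()
    chromosomes = marker_map["chromosome"].to_numpy()
    for grp in _redundancy_groups(g.dosages, chromosomes, positions, survivors):
        idx = survivors[np.asarray(grp)]
        # keep max MAF; tie -> lower position
        order = sorted(idx, key=lambda j: (-mafs[j], positions[j]))
        for j in order[1:]:
            reason[j] = "redundancy"

    keep = reason == ""
    if not keep.any():
        raise ValueError("all SNPs removed by QC")
    for j in np.flatnonzero(~keep):
        removed.append((g.snp_ids[j], reason[j]))
    report.removed_snps = pd.DataFrame(removed, columns=["snp_id", "reason"])
    g_out = g.subset(col_mask=keep)
    map_out = marker_map.loc[keep].reset_index(drop=True)
    return g_out, map_out, report


def impute_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing entries with the per-SNP expected dosage 2p."""
    if not g.has_missing():
        return g
    dosages = g.dosages.copy()
    col_mean = np.nanmean(dosages, axis=0)
    nan_rows, nan_cols = np.nonzero(np.isnan(dosages))
    dosages[nan_rows, nan_cols] = col_mean[nan_cols]
    return GenotypeMatrix(
        ids=g.ids,
        snp_ids=g.snp_ids,
        dosages=dosages,
        coding_center=g.coding_center,
        coding_scale=g.coding_scale,
    )


def run_qc(g: GenotypeMatrix, marker_map: pd.DataFrame):
    """Full single-pass QC: individuals, then SNPs, then imputation."""
    g, ind_report = qc_individuals(g)
    g, marker_map, snp_report = qc_snps(g, marker_map)
    g = impute_missing(g)
    report = QcReport(
        removed_individuals=ind_report.removed_individuals,
        removed_snps=snp_report.removed_snps,
        filter_order=["individuals:" + r for r in ind_report.filter_order]
        + ["snps:" + r for r in snp_report.filter_order],
    )
    return g, marker_map, report
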