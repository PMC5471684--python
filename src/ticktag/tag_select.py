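"""Four-step tag-SNP panel construction within top windows.

1. *Top SNPs*: the maximum-MF SNP of each top window (ties broken by
   higher TL, then higher MAF, then lower position).  The minimum MF
   among top SNPs becomes the MF threshold.
2. *MF augmentation*: every SNP in a top window with MF strictly above
   that threshold joins the panel.
3. *TL augmentation*: the minimum defined TL over the pre-selected set
   becomes the TL threshold; SNPs in top windows with TL strictly above
   it join.
4. *LD pruning*: among the selected SNPs, while any pair has r^2 > 0.4
   (squared Pearson correlation of dosages, composite LD) the pair with
   the largest r^2 is resolved by dropping its lower-MAF member (tie:
   drop the higher position).

All tie-breaks are deterministic, so identical inputs give identical
panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .bayes_core import PosteriorSummary
from .containers import GenotypeMatrix
from .genoqc import maf as _maf

R2_MAX_DEFAULT = 0.4


@dataclass
class TagPanel:
    """Selected tag SNPs with per-step provenance and exclusions."""

    snps: pd.DataFrame            # snp_id, chromosome, position_bp, mf, tl, maf, provenance
    excluded: pd.DataFrame        # snp_id, reason, partner
    mf_min: float
    tl_min: float
    r2_max: float

    @property
    def snp_ids(self) -> list:
        return list(self.snps["snp_id"])

    def __len__(self) -> int:
        return len(self.snps)


def candidate_table(
    summary: PosteriorSummary,
    marker_map: pd.DataFrame,
    g: GenotypeMatrix,
    top_windows: pd.DataFrame,
) -> pd.DataFrame:
    """Per-SNP frame (MF, TL, MAF, window) restricted to top windows."""
    stats = summary.snp_frame().set_index("snp_id")
    rows = []
    pos = marker_map.set_index("snp_id")
    order = {s: j for j, s in enumerate(g.snp_ids)}
    for _, win in top_windows.iterrows():
        for s in win["snp_ids"]:
            rows.append(
                {
                    "snp_id": s,
                    "chromosome": pos.loc[s, "chromosome"],
                    "position_bp": int(pos.loc[s, "position_bp"]),
                    "window_id": int(win["window_id"]),
                    "mf": float(stats.loc[s, "mf"]),
                    "tl": float(stats.loc[s, "tl"]),
                    "maf": _maf(g.dosages[:, order[s]]),
                }
            )
    return pd.DataFrame(rows)


def pick_top_snps(candidates: pd.DataFrame):
    """Maximum-MF SNP per top window; returns (top snp_id set, mf_min).

    Ties on MF are broken by higher TL, then higher MAF, then lower
    position.
    """
    if len(candidates) == 0:
        raise ValueError("no top windows: cannot pick top SNPs")
    tops = []
    for _, grp in candidates.groupby("window_id", sort=True):
        grp = grp.copy()
        grp["_tl"] = grp["tl"].fillna(-np.inf)
        grp = grp.sort_values(
            by=["mf", "_tl", "maf", "position_bp"],
            ascending=[False, False, False, True],
            kind="mergesort",
        )
        tops.append(grp.iloc[0]["snp_id"])
    mf_by_snp = candidates.set_index("snp_id")["mf"]
    mf_min = float(mf_by_snp.loc[tops].min())
    return set(tops), mf_min


def augment_by_mf(candidates: pd.DataFrame, top_snps: set, mf_min: float) -> set:
    """Union of top SNPs and candidates with MF strictly above mf_min."""
    extra = set(candidates.loc[candidates["mf"] > mf_min, "snp_id"])
    return set(top_snps) | extra


def augment_by_tl(candidates: pd.DataFrame, preselected: set):
    """Add candidates with TL strictly above the minimum defined TL of the
    pre-selected set.  Returns (selected set, tl_min)."""
    if not preselected:
        raise ValueError("empty pre-selected set")
    pre = candidates[candidates["snp_id"].isin(preselected)]
    tls = pre["tl"].dropna()
    if len(tls) == 0:
        raise ValueError("TL undefined for every pre-selected SNP")
    tl_min = float(tls.min())
    extra = set(candidates.loc[candidates["tl"] > tl_min, "snp_id"])
    return set(preselected) | extra, tl_min


def ld_r2(col_i: np.ndarray, col_j: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage columns (composite LD)."""
    col_i = np.asarray(col_i, dtype=float)
    col_j = np.asarray(col_j, dtype=float)
    if col_i.std() == 0 or col_j.std() == 0:
        return np.nan
    r = np.corrcoef(col_i, col_j)[0, 1]
    return float(r * r)


def ld_prune(
    candidates: pd.DataFrame,
    selected: set,
    g: GenotypeMatrix,
    r2_max: float = R2_MAX_DEFAULT,
    mf_min: float = np.nan,
    tl_min: float = np.nan,
    protect_top_snps: bool = False,
    top_snps: Optional[set] = None,
) -> TagPanel:
    """Iteratively resolve r^2 > r2_max pairs, keeping the higher-MAF SNP.

    Offending pairs are processed in descending r^2 order; after each
    drop the remaining pairs are re-evaluated.  With
    ``protect_top_snps`` the per-window top SNPs are never dropped
    (default off: the printed rule keeps max-MAF unconditionally).
    """
    info = candidates.set_index("snp_id")
    order = {s: j for j, s in enumerate(g.snp_ids)}
    retained = sorted(selected, key=lambda s: (info.loc[s, "chromosome"], info.loc[s, "position_bp"]))
    protected = set(top_snps or ()) if protect_top_snps else set()
    excluded = []

    def worst_pair(snps):
        best = None
        for x in range(len(snps)):
            for yy in range(x + 1, len(snps)):
                a, b = snps[x], snps[yy]
                r2 = ld_r2(g.dosages[:, order[a]], g.dosages[:, order[b]])
                if np.isnan(r2) or r2 <= r2_max:
                    continue
                if best is None or r2 > best[0]:
                    best = (r2, a, b)
        return best

    while True:
        hit = worst_pair(retained)
        if hit is None:
            break
        r2, a, b = hit
        maf_a, maf_b = info.loc[a, "maf"], info.loc[b, "maf"]
        if a in protected and b not in protected:
            loser = b
        elif b in protected and a not in protected:
            loser = a
        elif maf_a < maf_b:
            loser = a
        elif maf_b < maf_a:
            loser = b
        else:  # MAF tie: drop the higher position
            pa = (info.loc[a, "chromosome"], info.loc[a, "position_bp"])
            pb = (info.loc[b, "chromosome"], info.loc[b, "position_bp"])
            loser = a if pa > pb else b
        winner = b if loser == a else a
        retained.remove(loser)
        excluded.append({"snp_id": loser, "reason": "ld_pruned", "partner": winner, "r2": r2})

    snps = info.loc[retained].reset_index()
    snps = snps.sort_values(["chromosome", "position_bp"], kind="mergesort").reset_index(drop=True)
    return TagPanel(
        snps=snps,
        excluded=pd.DataFrame(excluded, columns=["snp_id", "reason", "partner", "r2"]),
        mf_min=mf_min,
        tl_min=tl_min,
        r2_max=r2_max,
    )


def build_panel(
    summary: PosteriorSummary,
    marker_map: pd.DataFrame,
    g: GenotypeMatrix,
    top_windows: pd.DataFrame,
    r2_max: float = R2_MAX_DEFAULT,
    protect_top_snps: bool = False,
) -> TagPanel:
    """Run the full four-step selection and annotate provenance."""
    candidates = candidate_table(summary, marker_map, g, top_windows)
    top_snps, mf_min = pick_top_snps(candidates)
    mf_set = augment_by_mf(candidates, top_snps, mf_min)
    tl_set, tl_min = augment_by_tl(candidates, mf_set)
    panel = ld_prune(
        candidates, tl_set, g, r2_max=r2_max, mf_min=mf_min, tl_min=tl_min,
        protect_top_snps=protect_top_snps, top_snps=top_snps,
    )
    prov = []
    for s in panel.snps["snp_id"]:
        if s in top_snps:
            prov.append("top_snp")
        elif s in mf_set:
            prov.append("mf_add")
        else:
            prov.append("tl_add")
    panel.snps["provenance"] = prov
    return panel
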