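"""1-Mb window variance partitioning of the genomic signal.

SNPs are allocated to non-overlapping 1-Mb windows by physical map
order (half-open bins ``[k*1e6 + 1, (k+1)*1e6]`` on 1-based positions;
only non-empty windows are instantiated).  For each kept MCMC sample the
genomic value of window w is ``u_w = Z_w alpha_w``; its share of genetic
variance is ``var(u_w) / var(u_total)`` across individuals, and the
window's %Var is the posterior mean share x 100.  Because windows are in
LD, per-window shares need not sum exactly to 100; they do on
independent markers.

Top windows are those whose %Var reaches ``multiplier`` times the
equal-contribution expectation 100 / n_windows (default multiplier 5,
i.e. the 0.2% rule when 2519 windows are defined).
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .bayes_core import PosteriorSummary
from .containers import GenotypeMatrix

WINDOW_BP = 1_000_000


def assign_windows(marker_map: pd.DataFrame) -> Tuple[pd.DataFrame, np.ndarray]:
    """Allocate SNPs to 1-Mb windows.

    Returns a window skeleton table (window_id sequential in physical
    map order, chromosome, mb index, ``chr_Mb`` label, n_snp) and the
    per-SNP window index (0-based row into the table, aligned with the
    marker map).
    """
    if len(marker_map) == 0:
        raise ValueError("empty marker map")
    chrom = marker_map["chromosome"].to_numpy()
    pos = marker_map["position_bp"].to_numpy()
    mb = (pos - 1) // WINDOW_BP
    keys = list(zip(chrom, mb))
    seen = {}
    snp_window = np.empty(len(marker_map), dtype=np.intp)
    rows = []
    for i, key in enumerate(keys):
        if key not in seen:
            seen[key] = len(rows)
            rows.append(key)
        snp_window[i] = seen[key]
    table = pd.DataFrame(
        {
            "window_id": np.arange(1, len(rows) + 1),
            "chromosome": [c for c, _ in rows],
            "mb_index": [int(m) for _, m in rows],
            "chr_mb": [f"{c}_{int(m)}" for c, m in rows],
        }
    )
    counts = np.bincount(snp_window, minlength=len(rows))
    table["n_snp"] = counts
    table["snp_ids"] = [
        list(marker_map.loc[snp_window == w, "snp_id"]) for w in range(len(rows))
    ]
    return table, snp_window


def expected_window_share(n_windows: int) -> float:
    """Equal-contribution expectation, in percent: 100 / n_windows."""
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    return 100.0 / n_windows


def window_variance(
    summary: PosteriorSummary,
    g: GenotypeMatrix,
    windows: Optional[pd.DataFrame] = None,
    snp_window: Optional[np.ndarray] = None,
    marker_map: Optional[pd.DataFrame] = None,
    use_posterior_mean: bool = False,
    numerator: str = "variance",
) -> pd.DataFrame:
    """Fill the window table with posterior %Var shares.

    Per kept sample the share of each window is computed against the
    total genomic variance of that sample; samples with zero total
    genomic variance are skipped (count recorded in
    ``table.attrs['skipped_samples']``).  With ``use_posterior_mean``
    the shares are instead computed once from posterior-mean effects.

    ``numerator`` chooses how LD covariance between windows is treated:
    ``"variance"`` (default) uses the raw window variance var(u_w), so
    shares need not sum exactly to 100 under LD; ``"covariance"`` uses
    cov(u_w, u_total), which splits the between-window covariance and
    sums to 100 exactly.
    """
    if numerator not in ("variance", "covariance"):
        raise ValueError("numerator must be 'variance' or 'covariance'")
    if windows is None or snp_window is None:
        if marker_map is None:
            raise ValueError("provide either (windows, snp_window) or marker_map")
        windows, snp_window = assign_windows(marker_map)
    order = {s: j for j, s in enumerate(g.snp_ids)}
    cols = np.array([order[s] for s in summary.snp_ids], dtype=np.intp)
    X = g.coded()[:, cols]
    X = X - X.mean(axis=0)

    n_w = len(windows)
    if use_posterior_mean:
        alphas = summary.effect_mean[None, :]
    else:
        alphas = summary.alpha_trace
    kept = alphas.shape[0]

    # total genomic values for all samples at once
    U = X @ alphas.T                            # (n, kept)
    var_tot = U.var(axis=0)
    good = var_tot > 0
    shares = np.zeros((kept, n_w))
    for w in range(n_w):
        sel = np.flatnonzero(snp_window == w)
        if len(sel) == 0:
            continue
        Uw = X[:, sel] @ alphas[:, sel].T       # (n, kept)
        if numerator == "variance":
            num = Uw.var(axis=0)
        else:
            num = ((Uw - Uw.mean(axis=0)) * (U - U.mean(axis=0))).mean(axis=0)
        shares[:, w] = np.divide(num, var_tot, out=np.zeros(kept), where=good)

    skipped = int((~good).sum())
    if good.any():
        pct = shares[good].mean(axis=0) * 100.0
    else:
        pct = np.zeros(n_w)

    table = windows.copy()
    table["pct_var"] = pct
    table.attrs["skipped_samples"] = skipped
    table.attrs["n_windows"] = n_w
    return table


def select_top_windows(table: pd.DataFrame, multiplier: float = 5.0) -> pd.DataFrame:
    """Windows whose %Var is at least multiplier x the uniform expectation,
    sorted by %Var descending with cumulative percentages filled."""
    n_windows = table.attrs.get("n_windows", len(table))
    threshold = multiplier * expected_window_share(n_windows)
    top = table[table["pct_var"] >= threshold].copy()
    top = top.sort_values("pct_var", ascending=False, kind="mergesort").reset_index(drop=True)
    top["cum_pct"] = top["pct_var"].cumsum()
    top.attrs["threshold"] = threshold
    top.attrs["n_windows"] = n_windows
    return top


def manhattan_plot(table: pd.DataFrame, path, multiplier: float = 5.0):
    """Window-level Manhattan-style plot of %Var against genome position."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_windows = table.attrs.get("n_windows", len(table))
    threshold = multiplier * expected_window_share(n_windows)
    fig, ax = plt.subplots(figsize=(9, 3.2))
    x = np.arange(len(table))
    chroms = table["chromosome"].to_numpy()
    uniq = list(dict.fromkeys(chroms))
    for k, c in enumerate(uniq):
        sel = chroms == c
        ax.scatter(x[sel], table.loc[sel, "pct_var"], s=8,
                   color="tab:blue" if k % 2 == 0 else "tab:orange")
    ax.axhline(threshold, color="grey", lw=1)
    ax.set_xlabel("1-Mb window (physical map order)")
    ax.set_ylabel("% genetic variance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
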