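"""Fivefold cross-validated genomic prediction with tag-SNP panels.

Animals are split into five groups either by K-means clustering on the
genomic relationship matrix (VanRaden method 1; clustering operates on
its leading principal components) or at random with near-equal sizes.
Each fold runs the entire discovery chain on the four training groups --
BayesB (pi = 0.99) GWAS, 1-Mb window calling, four-step tag selection --
then refits the panel SNP effects with BayesA on the training data and
predicts direct genomic values

    DGV_j = sum_i z_ji a_hat_i

for held-out animals.  Per-fold accuracy is the Legarra-style estimator
cor(DGV, DEBV)/sqrt(h2), with h2 the training-run posterior mean genomic
heritability of the model that produced the effects; pooling across
folds uses inverse-variance weights from Fisher-z standard errors.
Test individuals never enter training (checked by disjoint id-set
hashes).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from . import tag_select, window_gwas
from .bayes_core import McmcSettings, PosteriorSummary, PriorSpec, run_chain
from .containers import GenotypeMatrix


@dataclass
class CvPartition:
    method: str                 # "kmeans" | "random"
    assignment: np.ndarray      # group index per individual, 0..k-1
    k: int
    seed: int

    def groups(self):
        return [np.flatnonzero(self.assignment == c) for c in range(self.k)]


@dataclass
class AccuracyReport:
    fold_accuracy: np.ndarray
    fold_n: np.ndarray
    fold_panel_size: np.ndarray
    pooled_accuracy: float
    pooled_se: float
    truth_accuracy: Optional[np.ndarray] = None   # cor(DGV, tbv), simulation only
    clamped: bool = False
    panels: list = field(default_factory=list)
    degenerate_folds: list = field(default_factory=list)  # raw-correlation folds

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "fold": np.arange(1, len(self.fold_accuracy) + 1),
                "n_test": self.fold_n,
                "panel_size": self.fold_panel_size,
                "accuracy": self.fold_accuracy,
            }
        )
        if self.truth_accuracy is not None:
            df["truth_accuracy"] = self.truth_accuracy
        return df


def grm(g: GenotypeMatrix) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix.

    G = M M' / (2 sum p(1-p)) with M the dosage matrix centered by 2p.
    """
    dos = g.dosages
    if np.isnan(dos).any():
        raise ValueError("GRM requires complete genotypes")
    p = dos.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("need at least 2 polymorphic SNPs for a GRM")
    M = dos[:, poly] - 2.0 * p[poly]
    denom = 2.0 * float((p[poly] * (1 - p[poly])).sum())
    return (M @ M.T) / denom


def group_relationship_summary(G: np.ndarray, assignment: np.ndarray) -> pd.DataFrame:
    """Mean (+/- SD) within- and between-group genomic relationships."""
    rows = []
    k = int(assignment.max()) + 1
    for c in range(k):
        idx = np.flatnonzero(assignment == c)
        other = np.flatnonzero(assignment != c)
        within = G[np.ix_(idx, idx)][np.triu_indices(len(idx), k=1)]
        between = G[np.ix_(idx, other)].ravel()
        rows.append(
            {
                "group": c + 1,
                "n": len(idx),
                "within_mean": within.mean() if len(within) else np.nan,
                "within_sd": within.std() if len(within) else np.nan,
                "between_mean": between.mean() if len(between) else np.nan,
                "between_sd": between.std() if len(between) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def kmeans_partition(G: np.ndarray, k: int = 5, seed: int = 0, n_components: int = 10) -> CvPartition:
    """K-means on the leading principal components of the GRM."""
    n = G.shape[0]
    if n < k:
        raise ValueError(f"cannot split {n} individuals into {k} groups")
    n_components = min(n_components, n)
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1][:n_components]
    coords = vecs[:, order] * np.sqrt(np.abs(vals[order]))
    for attempt in range(5):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed + attempt)
        labels = km.fit_predict(coords)
        if len(np.unique(labels)) == k:
            break
    return CvPartition(method="kmeans", assignment=labels.astype(np.intp), k=k, seed=seed)


def random_partition(n: int, k: int = 5, seed: int = 0) -> CvPartition:
    """Seeded random split into k groups with sizes differing by <= 1."""
    if n < k:
        raise ValueError(f"cannot split {n} individuals into {k} groups")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=np.intp)
    assignment[perm] = np.arange(n) % k
    return CvPartition(method="random", assignment=assignment, k=k, seed=seed)


def dgv(g_test: GenotypeMatrix, effects: Dict[str, float] | pd.Series, panel_snp_ids) -> np.ndarray:
    """Direct genomic values: dot product of panel covariates and effects."""
    if isinstance(effects, pd.Series):
        effects = effects.to_dict()
    sub = g_test.select_snps(panel_snp_ids)   # raises if a panel SNP is absent
    a = np.array([effects[s] for s in panel_snp_ids], dtype=float)
    return sub.coded() @ a


def accuracy(dgv_values: np.ndarray, debv: np.ndarray, h2: float):
    """Legarra-style within-group accuracy: cor(DGV, DEBV)/sqrt(h2).

    Clamped to [-1, 1]; returns (value, clamped_flag).  NaN when either
    vector has zero variance.
    """
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must lie in (0, 1]")
    dgv_values = np.asarray(dgv_values, dtype=float)
    debv = np.asarray(debv, dtype=float)
    if len(dgv_values) < 10:
        raise ValueError("need at least 10 individuals for an accuracy estimate")
    if dgv_values.std() == 0 or debv.std() == 0:
        return np.nan, False
    r = float(np.corrcoef(dgv_values, debv)[0, 1]) / np.sqrt(h2)
    clamped = abs(r) > 1.0
    return float(np.clip(r, -1.0, 1.0)), clamped


def _idset_hash(ids) -> str:
    h = hashlib.sha256()
    for s in sorted(str(x) for x in ids):
        h.update(s.encode())
        h.update(b"\x00")
    return h.hexdigest()


def cross_validate(
    g: GenotypeMatrix,
    marker_map: pd.DataFrame,
    pheno: pd.DataFrame,
    partition: CvPartition,
    gwas_prior: Optional[PriorSpec] = None,
    gwas_settings: Optional[McmcSettings] = None,
    refit_settings: Optional[McmcSettings] = None,
    window_multiplier: float = 5.0,
    r2_max: float = tag_select.R2_MAX_DEFAULT,
    tbv: Optional[np.ndarray] = None,
    min_training: int = 20,
    h2_null_threshold: float = 0.02,
) -> AccuracyReport:
    """Fivefold cross-validation of the full discovery + prediction chain.

    Per fold: BayesB GWAS on training -> window variances -> top windows
    -> tag panel -> BayesA refit of panel effects on training -> DGV and
    Legarra accuracy on the held-out group.  ``tbv`` (simulation truth)
    adds a cor(DGV, tbv) column.

    The accuracy estimator divides cor(DGV, DEBV) by the square root of
    the response reliability: since cor(DGV, debv) = cor(DGV, u) x
    cor(u, debv) and cor(u, debv) = sqrt(r), this recovers the accuracy
    of the DGV as a predictor of the true breeding value u.  The
    reliability is taken from the pseudophenotype table's ``weight``
    column when present; otherwise the training-run posterior mean
    genomic h2 of the refit model is used as a fallback (that fallback
    understates the divisor when the panel captures only part of the
    genetic variance).  When the discovery GWAS finds essentially no
    heritable signal (posterior mean h2 below ``h2_null_threshold``),
    rescaling is meaningless and the fold reports the raw correlation,
    recorded in ``degenerate_folds``.
    """
    gwas_prior = PriorSpec() if gwas_prior is None else gwas_prior
    gwas_settings = McmcSettings(n_iter=4000, burn_in=1000, thin=5) if gwas_settings is None else gwas_settings
    refit_settings = refit_settings if refit_settings is not None else gwas_settings

    tab = pheno.set_index("individual_id").loc[list(g.ids)]
    y = tab["debv"].to_numpy(dtype=float)
    reliability = None
    if "weight" in tab.columns:
        w_col = tab["weight"].to_numpy(dtype=float)
        if np.all(np.isfinite(w_col)) and np.all((w_col > 0) & (w_col <= 1)):
            reliability = float(w_col.mean())

    windows, snp_window = window_gwas.assign_windows(marker_map)
    fold_acc, fold_n, fold_sz, truth_acc, panels = [], [], [], [], []
    degenerate_folds = []
    any_clamped = False

    for c, test_idx in enumerate(partition.groups()):
        train_mask = np.ones(g.n_individuals, dtype=bool)
        train_mask[test_idx] = False
        if train_mask.sum() < min_training:
            raise ValueError(f"fold {c}: fewer than {min_training} training individuals")
        g_train = g.subset(row_mask=train_mask)
        g_test = g.subset(row_mask=~train_mask)
        assert _idset_hash(g_train.ids) != _idset_hash(g_test.ids)
        assert not set(g_train.ids) & set(g_test.ids)

        gwas = run_chain(
            g_train, y[train_mask], prior=gwas_prior,
            settings=replace(gwas_settings, seed=gwas_settings.seed + c),
            method="bayesB",
        )
        wtab = window_gwas.window_variance(gwas, g_train, windows, snp_window)
        top = window_gwas.select_top_windows(wtab, multiplier=window_multiplier)
        if len(top) == 0:
            # no window clears the threshold: fall back to the single best
            top = wtab.sort_values("pct_var", ascending=False).head(1).copy()
            top["cum_pct"] = top["pct_var"].cumsum()
            top.attrs["n_windows"] = wtab.attrs.get("n_windows", len(wtab))
        panel = tag_select.build_panel(gwas, marker_map, g_train, top, r2_max=r2_max)
        panels.append(panel)

        g_panel_train = g_train.select_snps(panel.snp_ids)
        refit = run_chain(
            g_panel_train, y[train_mask],
            prior=replace(gwas_prior, pi=0.0),
            settings=replace(refit_settings, seed=refit_settings.seed + 100 + c),
            method="bayesA",
        )
        effects = pd.Series(refit.effect_mean, index=refit.snp_ids)
        pred = dgv(g_test, effects, panel.snp_ids)
        if gwas.h2_mean < h2_null_threshold:
            h2_train = 1.0  # no heritable signal found: report raw correlation
            degenerate_folds.append(c)
        elif reliability is not None:
            h2_train = reliability
        else:
            h2_train = min(max(refit.h2_mean, 1e-6), 1.0)
        acc, clamped = accuracy(pred, y[~train_mask], h2_train)
        any_clamped |= clamped
        fold_acc.append(acc)
        fold_n.append(len(test_idx))
        fold_sz.append(len(panel))
        if tbv is not None:
            t = np.asarray(tbv, dtype=float)[~train_mask]
            truth_acc.append(float(np.corrcoef(pred, t)[0, 1]) if t.std() > 0 and pred.std() > 0 else np.nan)

    fold_acc = np.asarray(fold_acc, dtype=float)
    fold_n = np.asarray(fold_n)
    # inverse-variance pooling with Fisher-z standard errors 1/sqrt(n-3)
    w = np.maximum(fold_n - 3, 1).astype(float)
    ok = ~np.isnan(fold_acc)
    pooled = float(np.sum(w[ok] * fold_acc[ok]) / np.sum(w[ok])) if ok.any() else np.nan
    pooled_se = float(1.0 / np.sqrt(np.sum(w[ok]))) if ok.any() else np.nan

    return AccuracyReport(
        fold_accuracy=fold_acc,
        fold_n=fold_n,
        fold_panel_size=np.asarray(fold_sz),
        pooled_accuracy=pooled,
        pooled_se=pooled_se,
        truth_accuracy=np.asarray(truth_acc) if tbv is not None else None,
        clamped=any_clamped,
        panels=panels,
        degenerate_folds=degenerate_folds,
    )
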