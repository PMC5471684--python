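"""Tag-SNP selection: printed rules, tie-breaks, brute-force equivalence."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ticktag.containers import GenotypeMatrix
from ticktag.tag_select import (
    augment_by_mf,
    augment_by_tl,
    ld_prune,
    ld_r2,
    pick_top_snps,
)


def _candidates(rows):
    return pd.DataFrame(rows, columns=["snp_id", "chromosome", "position_bp",
                                       "window_id", "mf", "tl", "maf"])


def _geno(columns: dict):
    snp_ids = list(columns)
    dos = np.column_stack([np.asarray(columns[s], dtype=float) for s in snp_ids])
    return GenotypeMatrix(ids=[f"i{k}" for k in range(dos.shape[0])],
                          snp_ids=snp_ids, dosages=dos)


# --- ld_r2 ---------------------------------------------------------------

def test_ld_r2_examples():
    a = np.array([0, 0, 2, 2], dtype=float)
    b = np.array([0, 2, 0, 2], dtype=float)
    assert ld_r2(a, a) == pytest.approx(1.0)
    assert ld_r2(a, b) == pytest.approx(0.0)
    x = np.array([0, 1, 2, 1, 0], dtype=float)
    y = np.array([0, 1, 1, 1, 0], dtype=float)
    # brute-force Pearson: r = cov/sd_x sd_y -> r^2 = 0.7619...
    r = np.corrcoef(x, y)[0, 1]
    assert ld_r2(x, y) == pytest.approx(r * r)
    assert ld_r2(x, y) == pytest.approx(0.7619, abs=1e-4)
    assert np.isnan(ld_r2(a, np.zeros(4)))


# --- step 1: top SNPs ----------------------------------------------------

def test_pick_top_snps_argmax_and_min():
    cands = _candidates([
        ("a", "1", 100, 1, 0.5, 1.0, 0.3),
        ("b", "1", 200, 1, 0.3, 1.1, 0.2),
        ("c", "1", 300, 1, 0.05, 0.9, 0.1),
        ("d", "2", 100, 2, 0.2, 0.95, 0.4),
    ])
    tops, mf_min = pick_top_snps(cands)
    assert tops == {"a", "d"}
    assert mf_min == pytest.approx(0.2)


def test_pick_top_snps_tie_breaks():
    # MF tie -> higher TL; TL tie -> higher MAF; then lower position
    cands = _candidates([
        ("a", "1", 300, 1, 0.4, 1.0, 0.3),
        ("b", "1", 200, 1, 0.4, 1.2, 0.1),
        ("c", "1", 100, 1, 0.4, 1.2, 0.1),
    ])
    tops, _ = pick_top_snps(cands)
    assert tops == {"c"}  # b vs c tie on TL and MAF -> lower position
    with pytest.raises(ValueError):
        pick_top_snps(cands.iloc[0:0])


# --- step 2: MF augmentation --------------------------------------------

def test_augment_by_mf_strict():
    cands = _candidates([
        ("t", "1", 1, 1, 0.5, 1.0, 0.3),
        ("x", "1", 2, 1, 0.25, 1.0, 0.3),
        ("y", "1", 3, 1, 0.2, 1.0, 0.3),
        ("z", "1", 4, 1, 0.15, 1.0, 0.3),
    ])
    out = augment_by_mf(cands, {"t"}, mf_min=0.2)
    assert out == {"t", "x"}  # strictly above 0.2 only
    assert augment_by_mf(cands, {"t"}, mf_min=0.6) == {"t"}


# --- step 3: TL augmentation --------------------------------------------

def test_augment_by_tl_strict_and_min():
    cands = _candidates([
        ("t1", "1", 1, 1, 0.5, 0.95, 0.3),
        ("t2", "1", 2, 1, 0.4, 1.2, 0.3),
        ("u", "1", 3, 1, 0.1, 0.95, 0.3),   # TL == tl_min: not added
        ("v", "1", 4, 1, 0.1, 1.0, 0.3),    # TL > tl_min: added
    ])
    out, tl_min = augment_by_tl(cands, {"t1", "t2"})
    assert tl_min == pytest.approx(0.95)
    assert out == {"t1", "t2", "v"}
    # undefined TL excluded from the minimum
    cands.loc[0, "tl"] = np.nan
    out, tl_min = augment_by_tl(cands, {"t1", "t2"})
    assert tl_min == pytest.approx(1.2)
    with pytest.raises(ValueError):
        augment_by_tl(cands.assign(tl=np.nan), {"t1"})


# --- step 4: LD pruning --------------------------------------------------

def _correlated_pair(rng, n, rho):
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
    to_dos = lambda z: np.digitize(z, [-0.6, 0.6]).astype(float)
    return to_dos(z1), to_dos(z2)


def test_ld_prune_keeps_higher_maf():
    rng = np.random.default_rng(0)
    a, b = _correlated_pair(rng, 400, 0.85)
    g = _geno({"a": a, "b": b})
    assert ld_r2(a, b) > 0.4
    cands = _candidates([
        ("a", "1", 100, 1, 0.5, 1.0, 0.25),
        ("b", "1", 200, 1, 0.4, 1.0, 0.40),
    ])
    panel = ld_prune(cands, {"a", "b"}, g)
    assert panel.snp_ids == ["b"]  # lower-MAF member dropped
    assert list(panel.excluded["snp_id"]) == ["a"]
    assert list(panel.excluded["reason"]) == ["ld_pruned"]


def test_ld_prune_identity_when_no_offending_pair():
    rng = np.random.default_rng(1)
    g = _geno({"a": rng.binomial(2, 0.5, 300).astype(float),
               "b": rng.binomial(2, 0.3, 300).astype(float)})
    cands = _candidates([
        ("a", "1", 100, 1, 0.5, 1.0, 0.25),
        ("b", "1", 200, 1, 0.4, 1.0, 0.40),
    ])
    panel = ld_prune(cands, {"a", "b"}, g)
    assert set(panel.snp_ids) == {"a", "b"}
    assert len(panel.excluded) == 0


def test_ld_prune_chain():
    """r2(1,2) and r2(2,3) offend, r2(1,3) does not; MAFs {0.1, 0.3, 0.2}:
    both neighbours of SNP2 are dropped, matching pairwise brute force."""
    rng = np.random.default_rng(2)
    n = 2000
    z2 = rng.standard_normal(n)
    z1 = 0.8 * z2 + 0.6 * rng.standard_normal(n)
    z3 = 0.8 * z2 - 0.6 * rng.standard_normal(n)
    to_dos = lambda z: np.digitize(z, [-0.6, 0.6]).astype(float)
    cols = {"s1": to_dos(z1), "s2": to_dos(z2), "s3": to_dos(z3)}
    g = _geno(cols)
    r12 = ld_r2(cols["s1"], cols["s2"])
    r23 = ld_r2(cols["s2"], cols["s3"])
    r13 = ld_r2(cols["s1"], cols["s3"])
    assert r12 > 0.4 and r23 > 0.4 and r13 < 0.4
    cands = _candidates([
        ("s1", "1", 100, 1, 0.5, 1.0, 0.1),
        ("s2", "1", 200, 1, 0.5, 1.0, 0.3),
        ("s3", "1", 300, 1, 0.5, 1.0, 0.2),
    ])
    panel = ld_prune(cands, {"s1", "s2", "s3"}, g)
    assert panel.snp_ids == ["s2"]


def _brute_force_prune(cands, selected, g, r2_max=0.4):
    """Independent oracle: repeatedly resolve the strongest offending pair."""
    info = cands.set_index("snp_id")
    order = {s: j for j, s in enumerate(g.snp_ids)}
    kept = set(selected)
    while True:
        pairs = []
        for a, b in itertools.combinations(sorted(kept), 2):
            r2 = ld_r2(g.dosages[:, order[a]], g.dosages[:, order[b]])
            if not np.isnan(r2) and r2 > r2_max:
                pairs.append((r2, a, b))
        if not pairs:
            return kept
        r2, a, b = max(pairs)
        if info.loc[a, "maf"] == info.loc[b, "maf"]:
            loser = a if info.loc[a, "position_bp"] > info.loc[b, "position_bp"] else b
        else:
            loser = a if info.loc[a, "maf"] < info.loc[b, "maf"] else b
        kept.discard(loser)


def test_staged_selection_matches_exhaustive_enumeration():
    """On random <=12-SNP fixtures the staged pipeline equals step-by-step
    brute-force enumeration."""
    rng = np.random.default_rng(7)
    for rep in range(10):
        m = int(rng.integers(4, 13))
        n = 300
        base = rng.standard_normal(n)
        cols, rows = {}, []
        for j in range(m):
            mix = rng.uniform(0, 0.95)
            z = mix * base + np.sqrt(1 - mix ** 2) * rng.standard_normal(n)
            d = np.digitize(z, [-0.7, 0.7]).astype(float)
            sid = f"s{j}"
            cols[sid] = d
            rows.append((sid, "1", 100 * (j + 1), int(j // 4) + 1,
                         float(rng.uniform(0.05, 0.8)),
                         float(rng.uniform(0.8, 1.5)),
                         float(np.minimum(d.mean() / 2, 1 - d.mean() / 2))))
        g = _geno(cols)
        cands = _candidates(rows)

        tops, mf_min = pick_top_snps(cands)
        # oracle step 1: per-window argmax by the documented tie-break
        oracle_tops = set()
        for w, grp in cands.groupby("window_id"):
            best = max(grp.itertuples(), key=lambda r: (r.mf, r.tl, r.maf, -r.position_bp))
            oracle_tops.add(best.snp_id)
        assert tops == oracle_tops
        assert mf_min == pytest.approx(min(cands.set_index("snp_id").loc[s, "mf"] for s in tops))

        sel_mf = augment_by_mf(cands, tops, mf_min)
        oracle_mf = oracle_tops | {r.snp_id for r in cands.itertuples() if r.mf > mf_min}
        assert sel_mf == oracle_mf

        sel_tl, tl_min = augment_by_tl(cands, sel_mf)
        oracle_tlmin = min(r.tl for r in cands.itertuples() if r.snp_id in sel_mf)
        oracle_tl = sel_mf | {r.snp_id for r in cands.itertuples() if r.tl > oracle_tlmin}
        assert sel_tl == oracle_tl

        panel = ld_prune(cands, sel_tl, g, mf_min=mf_min, tl_min=tl_min)
        assert set(panel.snp_ids) == _brute_force_prune(cands, sel_tl, g)
        # no retained pair offends
        order = {s: j for j, s in enumerate(g.snp_ids)}
        for a, b in itertools.combinations(panel.snp_ids, 2):
            r2 = ld_r2(g.dosages[:, order[a]], g.dosages[:, order[b]])
            assert np.isnan(r2) or r2 <= 0.4


def test_determinism(small_chain, small_pop):
    import ticktag as tt

    table = tt.window_variance(small_chain, small_pop["g"], marker_map=small_pop["map"])
    top = tt.select_top_windows(table, multiplier=3)
    if len(top) == 0:
        top = table.sort_values("pct_var", ascending=False).head(2).copy()
        top["cum_pct"] = top["pct_var"].cumsum()
    p1 = tt.build_panel(small_chain, small_pop["map"], small_pop["g"], top)
    p2 = tt.build_panel(small_chain, small_pop["map"], small_pop["g"], top)
    assert p1.snp_ids == p2.snp_ids
    assert p1.mf_min == p2.mf_min and p1.tl_min == p2.tl_min
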