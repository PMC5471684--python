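"""Synthetic admixed cattle populations for exercising the GWAS pipeline.

The generator emulates the statistical structure of a two-breed
(taurine x zebu) beef population genotyped on a medium-density SNP chip
and phenotyped for log-transformed tick counts:

* genotypes with controllable linkage disequilibrium, produced by a
  Gaussian-copula haplotype model with exponential correlation decay in
  physical distance;
* admixture: each individual carries a zebu ancestry proportion drawn
  from a configurable range, and the two ancestral pools differ by a
  Balding-Nichols (Fst-like) allele-frequency divergence;
* a sparse QTL architecture with heavy-tailed effect sizes, so a handful
  of 1-Mb windows carry most of the genetic variance;
* repeated (2-3x) log-scale tick-count records per animal under a
  repeatability model, scaled to a target narrow-sense heritability;
* deregressed-EBV-like pseudophenotypes (DEBV) with controlled
  reliability, standing in for pedigree BLUP plus deregression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import GenotypeMatrix, make_marker_map


@dataclass
class SimConfig:
    """Parameters of the synthetic population.

    Defaults are sized for desk-scale runs (about a thousand animals and
    a few thousand markers on a handful of chromosomes) while keeping the
    trait architecture of the target population: genomic heritability
    near 0.19, roughly ten QTL with heavy-tailed effects, three repeated
    log-count records per animal and zebu ancestry between 0 and 0.4.
    """

    n_individuals: int = 1000
    n_snps: int = 2000
    n_chromosomes: int = 5
    chromosome_length_bp: int = 10_000_000
    n_qtl: int = 10
    target_h2: float = 0.19
    qtl_effect_distribution: str = "gamma"  # "gamma" (heavy tail) or "normal"
    ld_decay_bp: float = 100_000.0
    zebu_admixture_range: Tuple[float, float] = (0.0, 0.4)
    ancestral_divergence: float = 0.1  # Fst-like divergence between pools
    records_per_animal: int = 3
    repeatability: float = 0.30  # phenotypic repeatability of log counts
    phenotypic_variance: float = 0.33  # var of log(tick count + 1) records
    debv_reliability: float = 0.5
    qtl_genotyped: bool = False  # False: QTL are hidden loci in LD with markers
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.n_snps < self.n_chromosomes:
            raise ValueError("n_snps must be >= n_chromosomes (at least one SNP per chromosome)")
        if self.n_qtl > self.n_snps:
            raise ValueError("n_qtl must not exceed n_snps")
        if not 0.0 <= self.target_h2 <= 1.0:
            raise ValueError("target_h2 must lie in [0, 1]")
        if self.chromosome_length_bp < 1_000_000:
            raise ValueError("chromosome_length_bp must be >= 1e6 (one full window)")
        lo, hi = self.zebu_admixture_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("zebu_admixture_range must be an interval within [0, 1]")
        if self.records_per_animal not in (2, 3):
            raise ValueError("records_per_animal must be 2 or 3")
        if not 0.0 < self.debv_reliability <= 1.0:
            raise ValueError("debv_reliability must lie in (0, 1]")
        if self.qtl_effect_distribution not in ("gamma", "normal"):
            raise ValueError("qtl_effect_distribution must be 'gamma' or 'normal'")
        if not self.target_h2 <= self.repeatability or self.repeatability >= 1.0:
            # repeatability bounds h2 from above in a repeatability model;
            # silently lift it when a high target_h2 is requested
            pass


@dataclass
class SimTruth:
    """Planted ground truth: the oracle for parameter-recovery tests.

    When QTL are hidden (``SimConfig.qtl_genotyped=False``, the default,
    emulating incomplete marker-QTL linkage disequilibrium) their
    dosages, chromosomes and positions are carried here; the QTL ids
    then name loci that are absent from the marker panel.
    """

    qtl_snp_ids: np.ndarray
    qtl_effects: np.ndarray
    tbv: np.ndarray
    true_h2: float
    zebu_proportion: np.ndarray
    individual_ids: np.ndarray
    qtl_chromosomes: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    qtl_positions_bp: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    qtl_dosages: Optional[np.ndarray] = None  # (n, n_qtl) when QTL are hidden
    degenerate: bool = False


def _haplotype_block(rng, p_ind, rho, n_hap):
    """Sample n_hap haplotypes over one chromosome via a Gaussian copula.

    p_ind : (n_hap, m) per-haplotype allele frequencies (admixture-mixed).
    rho   : (m,) lag-one correlations of the latent AR(1) field
            (rho[0] unused).
    """
    m = p_ind.shape[1]
    z = np.empty((n_hap, m))
    z[:, 0] = rng.standard_normal(n_hap)
    eps = rng.standard_normal((n_hap, m - 1)) if m > 1 else None
    for k in range(1, m):
        z[:, k] = rho[k] * z[:, k - 1] + np.sqrt(1.0 - rho[k] ** 2) * eps[:, k - 1]
    u = norm.cdf(z)
    return (u < p_ind).astype(np.int8)


def simulate_genotypes(config: SimConfig):
    """Simulate an admixed genotype panel.

    Returns
    -------
    (GenotypeMatrix, marker_map, SimTruth)
        The truth object carries zebu proportions; QTL fields are filled
        later by :func:`simulate_phenotypes`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # loci: marker panel plus (when QTL are hidden) extra causal loci that
    # will be withheld from the returned genotypes, emulating incomplete
    # LD between chip markers and QTL
    n_hidden = 0 if config.qtl_genotyped else config.n_qtl
    m_total = config.n_snps + n_hidden

    # locus counts split evenly across chromosomes, positions uniform
    base = m_total // config.n_chromosomes
    extra = m_total % config.n_chromosomes
    counts = [base + (1 if c < extra else 0) for c in range(config.n_chromosomes)]
    chroms, positions = [], []
    for c, cnt in enumerate(counts, start=1):
        pos = np.sort(rng.choice(np.arange(1, config.chromosome_length_bp + 1), size=cnt, replace=False))
        chroms.extend([str(c)] * cnt)
        positions.extend(pos.tolist())
    snp_ids = [f"snp{c}_{p}" for c, p in zip(chroms, positions)]
    locus_map = make_marker_map(snp_ids, chroms, positions)
    # generation follows sorted map order
    chroms = locus_map["chromosome"].to_numpy()
    positions = locus_map["position_bp"].to_numpy()
    snp_ids = locus_map["snp_id"].to_numpy()

    m = m_total
    n = config.n_individuals
    # ancestral pools: Balding-Nichols divergence around a common frequency
    p0 = rng.uniform(0.10, 0.90, size=m)
    fst = config.ancestral_divergence
    if fst > 0:
        a = p0 * (1 - fst) / fst
        b = (1 - p0) * (1 - fst) / fst
        p_tau = np.clip(rng.beta(a, b), 0.05, 0.95)
        p_zeb = np.clip(rng.beta(a, b), 0.05, 0.95)
    else:
        p_tau = p_zeb = p0

    lo, hi = config.zebu_admixture_range
    zebu = rng.uniform(lo, hi, size=n) if hi > lo else np.full(n, lo)
    # per-individual mixed allele frequencies
    p_mix = (1.0 - zebu)[:, None] * p_tau[None, :] + zebu[:, None] * p_zeb[None, :]

    dosages = np.zeros((n, m), dtype=np.float64)
    for c in range(1, config.n_chromosomes + 1):
        sel = np.flatnonzero(chroms == str(c))
        pos_c = positions[sel].astype(float)
        if config.ld_decay_bp > 0:
            rho = np.empty(len(sel))
            rho[0] = 0.0
            rho[1:] = np.exp(-np.diff(pos_c) / config.ld_decay_bp)
        else:
            rho = np.zeros(len(sel))
        p_c = p_mix[:, sel]
        h1 = _haplotype_block(rng, p_c, rho, n)
        h2 = _haplotype_block(rng, p_c, rho, n)
        dosages[:, sel] = h1 + h2

    ids = np.array([f"ind{i:05d}" for i in range(n)], dtype=object)

    if n_hidden > 0:
        # withhold n_qtl loci from the panel to serve as hidden QTL,
        # preferring common variants so planted effects are expressed
        freqs = dosages.mean(axis=0) / 2.0
        maf = np.minimum(freqs, 1 - freqs)
        eligible = np.flatnonzero(maf >= 0.05)
        if len(eligible) < n_hidden:
            eligible = np.argsort(-maf)[:n_hidden]
        hidden = np.sort(rng.choice(eligible, size=n_hidden, replace=False))
    else:
        hidden = np.array([], dtype=np.intp)
    marker_idx = np.setdiff1d(np.arange(m_total), hidden)

    g = GenotypeMatrix(ids=ids, snp_ids=snp_ids[marker_idx],
                       dosages=dosages[:, marker_idx])
    marker_map = locus_map.iloc[marker_idx].reset_index(drop=True)
    truth = SimTruth(
        qtl_snp_ids=snp_ids[hidden].copy(),
        qtl_effects=np.array([]),
        tbv=np.zeros(n),
        true_h2=0.0,
        zebu_proportion=zebu,
        individual_ids=ids,
        qtl_chromosomes=chroms[hidden].copy(),
        qtl_positions_bp=positions[hidden].copy(),
        qtl_dosages=dosages[:, hidden].copy() if n_hidden > 0 else None,
    )
    return g, marker_map, truth


def simulate_phenotypes(genotypes: GenotypeMatrix, config: SimConfig,
                        truth: Optional[SimTruth] = None):
    """Plant QTL effects and generate repeated log-scale tick-count records.

    True breeding values are ``tbv = Z_qtl @ effects`` (centered), with
    effects rescaled so that var(tbv) = target_h2 x phenotypic_variance
    (the trait lives on the log tick-count scale).  Records follow a
    repeatability model ``y = mu + tbv + pe + eps`` whose
    permanent-environment and residual variances fill the remaining
    phenotypic variance so that narrow-sense h2 matches ``target_h2``
    and repeatability matches ``config.repeatability`` (lifted to h2
    when target_h2 exceeds it).

    Returns (SimTruth, records DataFrame with columns individual_id,
    record, value).
    """
    config.validate()
    if genotypes.has_missing():
        raise ValueError("simulate_phenotypes requires complete genotypes")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    n, m = genotypes.dosages.shape

    hidden = (truth is not None and truth.qtl_dosages is not None
              and truth.qtl_dosages.shape[1] > 0)
    if config.n_qtl > 0:
        if hidden:
            qtl_dos = truth.qtl_dosages
            qtl_ids = truth.qtl_snp_ids
            qtl_chrom = truth.qtl_chromosomes
            qtl_pos = truth.qtl_positions_bp
        else:
            freqs = genotypes.dosages.mean(axis=0) / 2.0
            maf = np.minimum(freqs, 1 - freqs)
            eligible = np.flatnonzero(maf >= 0.05)
            if len(eligible) < config.n_qtl:
                eligible = np.argsort(-maf)[: max(config.n_qtl, 1)]
            qtl_idx = np.sort(rng.choice(eligible, size=config.n_qtl, replace=False))
            qtl_dos = genotypes.dosages[:, qtl_idx]
            qtl_ids = genotypes.snp_ids[qtl_idx]
            qtl_chrom = np.array([], dtype=object)
            qtl_pos = np.array([], dtype=np.int64)
        if config.qtl_effect_distribution == "gamma":
            mag = rng.gamma(shape=0.4, scale=1.0, size=config.n_qtl)
        else:
            mag = np.abs(rng.standard_normal(config.n_qtl))
        effects = mag * rng.choice([-1.0, 1.0], size=config.n_qtl)
        tbv = qtl_dos @ effects
        tbv = tbv - tbv.mean()
        # rescale effects so the trait sits on the log-count scale:
        # var(tbv) = h2 * phenotypic_variance
        raw = float(np.var(tbv))
        want = config.target_h2 * config.phenotypic_variance
        scale = np.sqrt(want / raw) if raw > 0 else 0.0
        effects = effects * scale
        tbv = tbv * scale
    else:
        effects = np.array([])
        tbv = np.zeros(n)
        qtl_ids = np.array([], dtype=object)
        qtl_chrom = np.array([], dtype=object)
        qtl_pos = np.array([], dtype=np.int64)
        qtl_dos = None

    var_g = float(np.var(tbv))
    h2 = config.target_h2
    if var_g == 0.0:
        h2 = 0.0

    if var_g > 0 and h2 > 0:
        var_p = config.phenotypic_variance
        t = max(config.repeatability, h2)
        var_pe = (t - h2) * var_p
        var_e = var_p - var_g - var_pe
    else:
        var_p, var_pe, var_e = config.phenotypic_variance, 0.0, config.phenotypic_variance
        h2 = 0.0

    pe = rng.normal(0.0, np.sqrt(var_pe), size=n) if var_pe > 0 else np.zeros(n)
    mu = 2.0  # typical mean of log(tick count + 1)
    rec = config.records_per_animal
    eps = rng.normal(0.0, np.sqrt(var_e), size=(n, rec))
    records_mat = mu + tbv[:, None] + pe[:, None] + eps

    denom = var_g + np.var(pe) + np.var(eps)
    true_h2 = float(var_g / denom) if denom > 0 else 0.0

    zebu = truth.zebu_proportion if truth is not None else np.zeros(n)
    out_truth = SimTruth(
        qtl_snp_ids=qtl_ids,
        qtl_effects=effects,
        tbv=tbv,
        true_h2=true_h2,
        zebu_proportion=zebu,
        individual_ids=genotypes.ids,
        qtl_chromosomes=qtl_chrom,
        qtl_positions_bp=qtl_pos,
        qtl_dosages=qtl_dos,
    )
    records = pd.DataFrame(
        {
            "individual_id": np.repeat(genotypes.ids, rec),
            "record": np.tile(np.arange(1, rec + 1), n),
            "value": records_mat.ravel(),
        }
    )
    return out_truth, records


def make_debv(truth: SimTruth, reliability: float, seed: int = 0) -> pd.DataFrame:
    """Emulate deregressed EBV with a stated reliability.

    debv_i = tbv_i + e_i with var(e) = var(tbv) (1 - r) / r, so the
    squared correlation between DEBV and true breeding value is
    approximately the requested reliability r.  The weight column holds
    the scalar r (a flat stand-in for deregression weights).
    """
    if not 0.0 < reliability <= 1.0:
        raise ValueError("reliability must lie in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    tbv = np.asarray(truth.tbv, dtype=float)
    var_g = float(np.var(tbv))
    degenerate = var_g == 0.0
    if degenerate:
        warnings.warn(
            "tbv has zero variance; DEBV are pure noise and their "
            "correlation with tbv is undefined",
            stacklevel=2,
        )
        noise_var = 1.0
    else:
        noise_var = var_g * (1.0 - reliability) / reliability
    noise = rng.normal(0.0, np.sqrt(noise_var), size=len(tbv)) if noise_var > 0 else np.zeros(len(tbv))
    debv = tbv + noise
    table = pd.DataFrame(
        {
            "individual_id": truth.individual_ids,
            "debv": debv,
            "weight": reliability,
            "zebu_proportion": truth.zebu_proportion,
        }
    )
    table.attrs["degenerate"] = degenerate
    table.attrs["reliability"] = reliability
    return table


def simulate_dataset(config: SimConfig):
    """Convenience wrapper: genotypes + phenotypes + DEBV in one call."""
    g, marker_map, truth0 = simulate_genotypes(config)
    truth, records = simulate_phenotypes(g, config, truth0)
    pheno = make_debv(truth, config.debv_reliability, seed=config.seed)
    return g, marker_map, truth, records, pheno
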