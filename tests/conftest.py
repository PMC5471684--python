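"""Shared fixtures: small seeded synthetic populations.

Everything is generated programmatically; the only stored fixture is the
published 48-window GWAS summary table under tests/data/.
"""

from pathlib import Path

import numpy as np
import pytest

import ticktag as tt

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def small_pop():
    """400 animals x 400 SNPs on 4 chromosomes, default architecture."""
    cfg = tt.SimConfig(
        n_individuals=400, n_snps=400, n_chromosomes=4,
        chromosome_length_bp=4_000_000, seed=11,
    )
    g, marker_map, truth, records, pheno = tt.simulate_dataset(cfg)
    g = tt.impute_missing(g)
    return {"config": cfg, "g": g, "map": marker_map, "truth": truth,
            "records": records, "pheno": pheno}


@pytest.fixture(scope="session")
def small_chain(small_pop):
    """A short seeded BayesB chain on the small population."""
    return tt.run_chain(
        small_pop["g"], small_pop["pheno"],
        settings=tt.McmcSettings(n_iter=800, burn_in=200, seed=42),
        method="bayesB",
    )


@pytest.fixture(scope="session")
def published_windows():
    """The published 48-row top-window summary (real-data GWAS output)."""
    import pandas as pd

    return pd.read_csv(DATA_DIR / "top_windows_published.tsv", sep="\t")
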