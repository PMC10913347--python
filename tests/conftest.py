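import numpy as np
import pandas as pd
import pytest

from crpfrail.synthetic import (
    CohortConfig,
    GwasPairConfig,
    generate_cohort,
    generate_instruments,
    generate_sumstats_pair,
    make_ld_reference,
)


@pytest.fixture(scope="session")
def small_cohort():
    """3000-subject cohort with the default (study-like) settings."""
    return generate_cohort(CohortConfig(n_subjects=3000, seed=42))


@pytest.fixture(scope="session")
def sumstats_pair():
    """Default-condition 20k-SNP summary-statistics pair with LD reference."""
    cfg = GwasPairConfig(n_snps=20_000, seed=11)
    ld = make_ld_reference(cfg.n_snps, cfg.ld_block_size, cfg.ld_r_within)
    exp_tab, out_tab, truth = generate_sumstats_pair(cfg, ld)
    return cfg, ld, exp_tab, out_tab, truth


@pytest.fixture
def clean_instruments():
    """200 valid instruments, causal effect 0.06, no pleiotropy."""
    return generate_instruments(n_instruments=200, causal_beta=0.06, seed=7)


def toy_sumstats(n=20, seed=0, frac_sig=0.5):
    """Small handmade summary-statistics table for clumping/harmonization."""
    rng = np.random.default_rng(seed)
    p = np.where(rng.random(n) < frac_sig, rng.uniform(1e-12, 4e-8, n), rng.uniform(1e-6, 1, n))
    z = rng.standard_normal(n)
    se = np.full(n, 0.01)
    return pd.DataFrame(
        {
            "SNP": [f"rs{i}" for i in range(n)],
            "CHR": rng.integers(1, 3, n),
            "BP": rng.integers(1, 2_000_000, n),
            "A1": rng.choice(list("ACGT"), n),
            "A2": "G",
            "EAF": rng.uniform(0.1, 0.9, n),
            "BETA": z * se,
            "SE": se,
            "P": p,
            "N": 100_000,
        }
    )
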