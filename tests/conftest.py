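"""Shared fixtures: small synthetic studies reused across the suite."""

import numpy as np
import pandas as pd
import pytest

import pleiofactor as pf


def make_sumstats(
    n=6, seed=0, chrom=1, start=1_000_000, spacing=10_000, trait="t"
) -> pf.SummaryStats:
    """Tiny hand-sized summary statistics for unit tests."""
    rng = np.random.default_rng(seed)
    beta = rng.normal(0, 0.02, n)
    se = np.full(n, 0.01)
    df = pd.DataFrame(
        {
            "snp": [f"rs{i+1}" for i in range(n)],
            "chrom": chrom,
            "pos": start + spacing * np.arange(n),
            "a1": "A",
            "a2": "G",
            "eaf": rng.uniform(0.1, 0.9, n),
            "beta": beta,
            "se": se,
            "n": 10_000,
            "n_cases": 1_000,
        }
    )
    return pf.SummaryStats(df, trait=trait)


@pytest.fixture(scope="session")
def pure_factor_study():
    """Pure common-factor architecture: all genetic covariance shared,
    no trait-specific effects, no sample overlap. M=20,000, N=50,000."""
    cfg = pf.SimConfig(
        n_blocks=400, snps_per_block=50, n1=50_000, n2=50_000,
        n_overlap=0, pheno_corr_overlap=0.0, seed=101,
        var_factor=0.13, var_unique_1=0.0, var_unique_2=0.0, s_sel=0.0,
    )
    panel, truth, s1, s2 = pf.simulate_study(cfg)
    ld = pf.compute_ld_scores(panel)
    gencov = pf.multivariable_ldsc(s1, s2, ld)
    # same estimate but with the sample-overlap term at its generative
    # value (zero here): isolates per-SNP statistics from intercept noise
    gencov_known = pf.multivariable_ldsc(s1, s2, ld)
    gencov_known.intercepts[0, 1] = gencov_known.intercepts[1, 0] = cfg.rho_overlap
    return dict(cfg=cfg, panel=panel, truth=truth, s1=s1, s2=s2, ld=ld,
                gencov=gencov, gencov_known=gencov_known)


@pytest.fixture(scope="session")
def mixed_study():
    """Shared factor plus trait-specific components (r_g ~ 0.3),
    moderate polygenicity. M=20,000, N=50,000."""
    cfg = pf.SimConfig(
        n_blocks=400, snps_per_block=50, n1=50_000, n2=50_000,
        n_overlap=0, pheno_corr_overlap=0.0, seed=202,
        var_factor=0.06, var_unique_1=0.14, var_unique_2=0.14, s_sel=0.0,
    )
    panel, truth, s1, s2 = pf.simulate_study(cfg)
    ld = pf.compute_ld_scores(panel)
    return dict(cfg=cfg, panel=panel, truth=truth, s1=s1, s2=s2, ld=ld)
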