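import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from meqtlkit import synthetic as syn

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def family_cohort():
    """Nuclear-family cohort (2 parents + 2 sibs) with moderate cis effects."""
    cfg = syn.SimConfig(
        seed=42, n_families=60, parents_per_family=2, sibs_per_family=(2, 2),
        n_unrelated=40, n_snps=300, n_cpgs=40, n_genes=8,
        p_cis_qtl=0.5, cis_effect_r2=0.10,
        h2_additive_range=(0.2, 0.5), household_var_range=(0.0, 0.1),
    )
    ped, K, H = syn.simulate_pedigree(cfg)
    geno = syn.simulate_genotypes(cfg, ped)
    cpgs, truth = syn.simulate_methylation(geno, K, H, cfg)
    expr, truth = syn.simulate_expression(geno, cpgs, cfg, truth)
    return dict(cfg=cfg, ped=ped, K=K, H=H, geno=geno, cpgs=cpgs,
                expr=expr, truth=truth)


@pytest.fixture(scope="session")
def unrelated_cohort():
    """Unrelated cohort used for oracle-equivalence and scan tests."""
    cfg = syn.SimConfig(
        seed=7, n_families=0, n_unrelated=400, n_snps=150, n_cpgs=50,
        n_genes=6, p_cis_qtl=0.4, cis_effect_r2=0.10,
    )
    ped, K, H = syn.simulate_pedigree(cfg)
    geno = syn.simulate_genotypes(cfg, ped)
    cpgs, truth = syn.simulate_methylation(geno, K, H, cfg)
    return dict(cfg=cfg, ped=ped, K=K, H=H, geno=geno, cpgs=cpgs, truth=truth)


def make_iv_table(rng, n_iv=5, theta=0.0, pleiotropy=0.0, se_gamma=0.02,
                  se_Gamma=0.02, gamma_scale=0.2, outlier_ratio=None):
    """Summary-level aligned IV table with known causal effect theta.

    Per IV: true gamma drawn around gamma_scale, observed with noise;
    Gamma = theta*gamma_true + pleiotropy + noise.  ``outlier_ratio`` plants
    one IV whose ratio is outlier_ratio * theta.
    """
    gamma_true = gamma_scale * (1.0 + 0.5 * rng.standard_normal(n_iv))
    gamma_true = np.where(np.abs(gamma_true) < 0.05, 0.1, gamma_true)
    gamma_hat = gamma_true + se_gamma * rng.standard_normal(n_iv)
    Gamma = theta * gamma_true + pleiotropy + se_Gamma * rng.standard_normal(n_iv)
    if outlier_ratio is not None:
        Gamma[0] = outlier_ratio * theta * gamma_true[0]
    return pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(n_iv)],
            "gamma": gamma_hat,
            "se_gamma": se_gamma,
            "Gamma": Gamma,
            "se_Gamma": se_Gamma,
            "maf": 0.3,
            "harmonization_action": "kept",
        }
    )
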