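import numpy as np
import pandas as pd
import pytest

from trialkit.synthdata import SimConfig, make_alpha_lattice, simulate_met, simulate_trial


@pytest.fixture(scope="session")
def small_cfg():
    # 24 genotypes x 2 reps on a 6 x 8 grid, 3 incomplete blocks per rep
    return SimConfig(
        n_geno=24, n_rep=2, n_block=3, rows=6, cols=8,
        sigma2_g=1.0, sigma2_e=1.0, sigma2_block=0.1, rho_r=0.4, rho_c=0.4, seed=42,
    )


@pytest.fixture(scope="session")
def small_trial(small_cfg):
    return simulate_trial(make_alpha_lattice(small_cfg), small_cfg)


@pytest.fixture(scope="session")
def met_cfg():
    return SimConfig(
        n_geno=30, n_rep=2, n_block=3, rows=10, cols=6, n_env=3,
        sigma2_g=0.8, sigma2_ge=0.3, sigma2_block=0.1, rho_r=0.3, rho_c=0.3, seed=7,
    )


@pytest.fixture(scope="session")
def met_table(met_cfg):
    return simulate_met(met_cfg)


def balanced_oneway(n_geno=50, n_rep=2, sigma2_g=1.0, sigma2_e=1.0, seed=0, mu=10.0):
    """Balanced one-way layout: n_geno genotypes x n_rep iid observations."""
    rng = np.random.default_rng(seed)
    geno = np.repeat([f"G{i:04d}" for i in range(n_geno)], n_rep)
    g = np.repeat(rng.normal(0, np.sqrt(sigma2_g), n_geno), n_rep)
    y = mu + g + rng.normal(0, np.sqrt(sigma2_e), n_geno * n_rep)
    return pd.DataFrame(
        {"genotype": geno, "rep": np.tile([f"R{j+1}" for j in range(n_rep)], n_geno), "y": y}
    )


def oneway_anova_components(tab, n_rep):
    """Method-of-moments (= REML under balance) variance components."""
    means = tab.groupby("genotype")["y"].mean()
    msb = n_rep * means.var(ddof=1)
    msw = (tab["y"] - tab["genotype"].map(means)).pow(2).sum() / (
        len(means) * (n_rep - 1)
    )
    return (msb - msw) / n_rep, msw
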