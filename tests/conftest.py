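import numpy as np
import pandas as pd
import pytest

from arcticfit.synthpop import SimConfig, simulate_population


@pytest.fixture(scope="session")
def small_sim():
    """One moderate simulated population shared across read-only tests."""
    cfg = SimConfig(n_founders=120, n_years=8, n_snps=400, seed=11)
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def tiny_panel():
    """3 individuals × 2 SNPs toy panel for hand-computed oracles."""
    from arcticfit.panel import GenotypePanel

    dosage = np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]])
    mmap = pd.DataFrame(
        {
            "scaffold": ["s1", "s1"],
            "pos": [100, 200],
            "a1": ["A", "C"],
            "a2": ["G", "T"],
            "snp_id": ["snp1", "snp2"],
        }
    )
    return GenotypePanel(dosage=dosage, marker_map=mmap, ids=np.array([0, 1, 2]))


def poisson_glmm_data(rng, b=0.3, year_sd=0.2, n=1500, n_years=12, intercept=-0.1):
    """Poisson log-link data with a TC/CC contrast and a year random intercept."""
    year = rng.integers(0, n_years, size=n)
    u = rng.normal(0, year_sd, size=n_years)
    geno = np.where(rng.random(n) < 0.25, "TC", "CC")
    eta = intercept + b * (geno == "TC") + u[year]
    y = rng.poisson(np.exp(eta))
    return pd.DataFrame(
        {"y": y.astype(float), "genotype": geno, "year": year.astype(str)}
    )
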