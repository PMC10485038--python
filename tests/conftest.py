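import numpy as np
import pandas as pd
import pytest

from sgasnf import (CohortConfig, FeatureBlock, generate_cohort,
                    inject_missingness)
from sgasnf.cohort import FeatureSpec


def two_cluster_config(n=120, gap_sd=3.0, n_features=3, seed=0, rho=0.2):
    """Compact two-phenotype config: `n_features` Gaussian features per
    domain, cluster means separated by `gap_sd` standard deviations."""
    feats = []
    for dom in ("clinical", "ultrasound", "cord_metabolomics",
                "maternal_metabolomics"):
        for j in range(n_features):
            feats.append(FeatureSpec(f"{dom[:4]}_f{j}", dom,
                                     loc=(0.0, gap_sd), scale=(1.0, 1.0)))
    return CohortConfig(n_patients=n, features=feats,
                        within_domain_correlation=rho, seed=seed)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-calibration cohort at reduced n, with missingness."""
    cfg = CohortConfig(n_patients=140, seed=11)
    cohort = generate_cohort(cfg)
    return inject_missingness(cohort, cfg.missing_rates, seed=12,
                              features=cfg.features)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def block_from_array(X, domain="clinical", names=None):
    X = np.asarray(X, dtype=float)
    if names is None:
        names = [f"f{j}" for j in range(X.shape[1])]
    return FeatureBlock(pd.DataFrame(X, columns=names), domain)
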