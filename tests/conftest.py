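"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from proteoscale.synthdata import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Modest cohort with modules, DE, covariates, and a causal block."""
    cfg = CohortConfig(seed=42, n_genes=120, module_sizes=(20, 20, 20),
                       n_modules=3, within_module_cor=0.6)
    expr, meta, geno, truth = generate_cohort(cfg)
    return cfg, expr, meta, geno, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with every planted effect switched off."""
    cfg = CohortConfig(seed=7, n_genes=100, n_modules=0, module_sizes=(),
                       de_effect=0.0, de_frac=0.0, covariate_effects={},
                       eqtl_beta=0.0, n_drivers=0, n_descendants_per_driver=0)
    expr, meta, geno, truth = generate_cohort(cfg)
    return cfg, expr, meta, geno, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_matrix():
    """Tiny deterministic matrix for closed-form oracles."""
    return pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0, 6.0, 5.0],
         [2.0, 1.0, 4.0, 3.0, 5.0, 7.0],
         [0.5, 0.6, 0.4, 0.8, 0.7, 0.9]],
        index=["f1", "f2", "f3"],
        columns=[f"s{i}" for i in range(6)],
    )
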