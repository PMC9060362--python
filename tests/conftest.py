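"""Shared fixtures: small simulated cohorts reused across test modules."""

import numpy as np
import pytest

import predlmm as pl


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-sample, 400-SNP four-subpopulation cohort with its dense GRM."""
    rng = np.random.default_rng(20240901)
    config = pl.CoalescentConfig(n_individuals=120, n_variants=400)
    freqs = pl.simulate_bn_frequencies(config, rng)
    dataset = pl.simulate_genotypes(freqs, config, rng)
    stats = pl.compute_standardization(dataset)
    grm = pl.compute_grm_full(dataset, stats)
    return {"config": config, "dataset": dataset, "stats": stats, "grm": grm}


@pytest.fixture
def tiny_dataset():
    """Hand-written 4-sample, 3-SNP dataset including a missing call."""
    g = np.array(
        [
            [0, 1, 2],
            [1, 2, 0],
            [2, 0, pl.MISSING],
            [0, 2, 1],
        ]
    )
    return pl.GenotypeDataset.from_array(g)
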