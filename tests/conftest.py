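"""Shared fixtures: small simulated populations reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from holoquail.kinship import build_A
from holoquail.preprocess import transform_genera
from holoquail.simdata import (
    SimConfig, default_true_params, simulate_population,
)


def small_config(**overrides):
    """A fast study-shaped configuration for unit tests."""
    base = dict(
        n_f2=300, n_phenotyped=300, n_chromosomes=4,
        chrom_lengths=[100.0, 80.0, 60.0, 40.0], n_snps=120,
        n_genera=10, n_otus=40, n_test_days=12, seed=20240915,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_pop():
    return simulate_population(small_config())


@pytest.fixture(scope="session")
def small_analysis(small_pop):
    """Pre-computed analysis inputs for the small population."""
    pop = small_pop
    A = build_A(pop.pedigree)
    ids = pop.sample_ids
    values, lambdas = transform_genera(pop.genus_abundances)
    pheno = pop.phenotypes.set_index("id").loc[ids]
    return {
        "pop": pop, "A": A, "ids": ids, "values": values,
        "lambdas": lambdas, "pheno": pheno,
        "test_day": pheno["test_day"],
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
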