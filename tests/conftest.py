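import numpy as np
import pandas as pd
import pytest

from pqtlkit import kinship as kin
from pqtlkit import synthetic as syn


@pytest.fixture(scope="session")
def family_cohort():
    """Study-sized family cohort: 130 families x 6 + 120 singletons = 900."""
    spec = syn.PedigreeSpec(n_families=130, offspring_per_family=4, n_singletons=120)
    ped = syn.simulate_pedigree(spec, seed=7)
    return ped, syn.expected_kinship(ped)


@pytest.fixture(scope="session")
def small_cohort():
    """60-individual cohort for exact-oracle comparisons."""
    spec = syn.PedigreeSpec(n_families=8, offspring_per_family=3, n_singletons=20)
    ped = syn.simulate_pedigree(spec, seed=3)
    K = syn.expected_kinship(ped)
    geno = syn.simulate_genotypes(ped, n_markers=300, seed=4)
    return ped, K, geno


@pytest.fixture(scope="session")
def medium_genotyped_cohort():
    """300 individuals with enough markers for kinship estimation checks."""
    spec = syn.PedigreeSpec(n_families=40, offspring_per_family=3, n_singletons=100)
    ped = syn.simulate_pedigree(spec, seed=5)
    K = syn.expected_kinship(ped)
    geno = syn.simulate_genotypes(ped, n_markers=20_000, seed=6)
    return ped, K, geno


@pytest.fixture(scope="session")
def grm_medium(medium_genotyped_cohort):
    _, _, geno = medium_genotyped_cohort
    return kin.genomic_kinship(geno)


def make_panel(models, kinship, seed, **kw):
    return syn.simulate_traits(models, kinship, seed=seed, **kw)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
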