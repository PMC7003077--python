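"""Shared fixtures: small synthetic panels reused across test modules."""

import logging

import numpy as np
import pandas as pd
import pytest

from ryegp import (
    SimulationConfig,
    TraitModel,
    calls_to_dosages,
    extract_blups,
    mean_impute,
    model2_spec,
    reml_fit,
    simulate_gbs_reads,
    simulate_population_set,
    simulate_trial,
    vanraden_grm,
)

logging.getLogger("ryegp").setLevel(logging.ERROR)

#: Across-location sodium variance components (strongly heritable mineral trait).
SODIUM = dict(sigma2_g=2.32e-3, sigma2_gs=0.25e-3, sigma2_e=3.93e-3)


@pytest.fixture(scope="session")
def small_founders():
    cfg = SimulationConfig(
        n_populations=2,
        families_per_population=(40, 40),
        n_snps=400,
        n_qtl=100,
        ancestral_pool_size=15,
        mean_depth=4.0,
        missing_rate=0.2,
        seed=7,
        traits={"Na": TraitModel(**SODIUM)},
    )
    return simulate_population_set(cfg)


@pytest.fixture(scope="session")
def small_reads(small_founders):
    return simulate_gbs_reads(small_founders)


@pytest.fixture(scope="session")
def small_trial(small_founders):
    return simulate_trial(small_founders)


@pytest.fixture(scope="session")
def standard_panel():
    """The standard simulated CV panel: 5 related populations, sodium-like trait.

    Returns (founders, reads, blups, grm, populations).
    """
    cfg = SimulationConfig(
        n_populations=5,
        families_per_population=60,
        n_snps=1500,
        n_qtl=400,
        ancestral_pool_size=15,
        mean_depth=6.0,
        missing_rate=0.15,
        seed=11,
        traits={"Na": TraitModel(**SODIUM)},
    )
    founders = simulate_population_set(cfg)
    reads = simulate_gbs_reads(founders)
    trial = simulate_trial(founders)
    fit = reml_fit(trial, model2_spec("Na"))
    blups = extract_blups(fit)
    grm = vanraden_grm(mean_impute(calls_to_dosages(reads)))
    pops = pd.Series(dict(zip(founders.individuals, founders.populations)))
    return founders, reads, blups, grm, pops


def halfsib_panel(n_pairs: int, m: int, seed: int, p_range=(0.1, 0.5)):
    """Half-sib pairs with known pedigree: each pair shares the mother.

    Returns (genotypes of the 2*n_pairs progeny, base allele frequencies,
    list of (i, j) half-sib index pairs).  Fathers are independent draws from
    the base frequencies, so the expected genomic relationship within a pair
    is 0.25.
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(*p_range, size=m)
    geno = np.empty((2 * n_pairs, m), dtype=np.int64)
    pairs = []
    for k in range(n_pairs):
        mother = rng.binomial(2, p)
        for j in range(2):
            maternal_gamete = rng.binomial(1, mother / 2.0)
            paternal_gamete = rng.binomial(1, p)
            geno[2 * k + j] = maternal_gamete + paternal_gamete
        pairs.append((2 * k, 2 * k + 1))
    return geno, p, pairs
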