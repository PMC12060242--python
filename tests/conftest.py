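import numpy as np
import pytest

from ensemble_gp.preprocess import concat_environments
from ensemble_gp.synthetic_data import (TraitArchitecture,
                                        assign_trait_architecture,
                                        simulate_marker_map,
                                        simulate_phenotypes,
                                        simulate_ril_population)


@pytest.fixture(scope="session")
def small_map():
    return simulate_marker_map(2, 30, 1_000_000, 120.0, seed=11)


@pytest.fixture(scope="session")
def dense_map():
    return simulate_marker_map(5, 60, 300_000, 150.0, seed=1)


@pytest.fixture(scope="session")
def population(dense_map):
    return simulate_ril_population(dense_map, 500, seed=2)


@pytest.fixture(scope="session")
def small_population(small_map):
    return simulate_ril_population(small_map, 200, seed=3)


@pytest.fixture(scope="session")
def additive_feature_table(population, dense_map):
    """Complete-genotype feature table for a 5-QTL additive trait, h2=0.8."""
    arch = assign_trait_architecture(dense_map, 5, 0, 1.0, (0.0, 1.0), 0.8,
                                     seed=7)
    pheno = simulate_phenotypes(population, arch, seed=8)
    return concat_environments(pheno, population), arch


def single_qtl_data(n_ril, qtl_index, beta, h2, seed, n_chrom=2,
                    markers_per_chrom=50):
    """One-QTL trait on a fresh population; returns (X, y, map)."""
    mm = simulate_marker_map(n_chrom, markers_per_chrom, 500_000, 120.0,
                             seed=seed)
    geno = simulate_ril_population(mm, n_ril, seed=seed + 1)
    arch = TraitArchitecture(mu=0.0, additive_qtl=((qtl_index, beta),),
                             epistatic_pairs=(), env_effects=(0.0,),
                             target_h2=h2)
    pheno = simulate_phenotypes(geno, arch, environments=1, seed=seed + 2)
    y = pheno.df["value"].to_numpy()
    return geno.dosages.astype(float), y, mm
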