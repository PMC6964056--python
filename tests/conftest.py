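"""Shared fixtures: tiny hand-checkable genotype sets and a desk-scale synthetic study."""

import warnings

import numpy as np
import pytest

import varkin as vk


@pytest.fixture(scope="session")
def desk_dataset():
    """One desk-scale simulated study (32 families, ~300 offspring, 800 loci)."""
    return vk.simulate_dataset(vk.desk_config(seed=5))


@pytest.fixture(scope="session")
def desk_kernels(desk_dataset):
    """NOIA and HWE kernel sets plus homozygosity for the desk dataset."""
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for approach in ("noia", "hwe"):
            kernels, hom = vk.prepare_kernels(
                desk_dataset.genotypes, approach, seed=5
            )
            out[approach] = kernels
    return out, hom


@pytest.fixture(scope="session")
def desk_data(desk_dataset, desk_kernels):
    _, hom = desk_kernels
    return desk_dataset.phenotypes.merge(hom, on="id")


@pytest.fixture(scope="session")
def desk_suites(desk_data, desk_kernels):
    """Eight-model suites fitted under both parameterizations on the desk study."""
    kernel_sets, _ = desk_kernels
    suites = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for approach in ("noia", "hwe"):
            suites[approach] = vk.fit_suite(
                "y",
                kernel_sets[approach],
                desk_data,
                approach=approach,
                fixed_factors=["cross", "batch", "day", "filleter"],
                dam_col="dam",
            )
    return suites


def genotypes_from_codes(codes):
    """GenotypeMatrix from a plain list-of-lists of codes (−1 = missing)."""
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    return vk.GenotypeMatrix(
        [f"i{r}" for r in range(n)], codes, [f"s{c}" for c in range(m)]
    )


@pytest.fixture
def hwe_locus():
    """Four individuals at one locus in exact HWE proportions (p = 0.5)."""
    return genotypes_from_codes([[0], [1], [1], [2]])
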