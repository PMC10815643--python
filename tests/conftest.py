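import numpy as np
import pytest

from episphere.config import RunConfig
from episphere.dataset import GenotypeDataset
from episphere.simulator import DiseaseModelSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset():
    """Three samples, two SNPs — the smallest valid panel."""
    return GenotypeDataset(
        genotypes=[[0, 2], [1, 1], [2, 0]],
        phenotype=[1, 0, 1],
        snp_names=["N0", "N1"],
    )


@pytest.fixture(scope="session")
def dnme_dataset():
    """A 100-SNP panel with a strong embedded purely-epistatic pair."""
    spec = DiseaseModelSpec(
        maf=0.4, h2=0.4, prevalence=None, marginal_effects=False, name="strong"
    )
    rng = np.random.default_rng(777)
    dataset, truth = generate_dataset(spec, 800, 800, 100, rng)
    return dataset, truth


@pytest.fixture(scope="session")
def null_dataset():
    """A panel with no embedded interaction (phenotype independent)."""
    rng = np.random.default_rng(4242)
    mafs = rng.uniform(0.05, 0.5, size=40)
    genotypes = rng.binomial(2, mafs[None, :], size=(400, 40)).astype(np.int8)
    phenotype = np.repeat([0, 1], 200).astype(np.int8)
    return GenotypeDataset(
        genotypes=genotypes,
        phenotype=rng.permutation(phenotype),
        snp_names=[f"N{i}" for i in range(40)],
    )


@pytest.fixture
def quick_config():
    return RunConfig(population_size=40, max_evaluations=2000, seed=9)
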