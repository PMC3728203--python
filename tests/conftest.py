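import numpy as np
import pytest

from ciseqtl import synthetic
from ciseqtl.datatypes import CovariateTable, GenotypeMatrix, SnpRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_genotypes(dosages, chrom="4", start=100, step=10, sample_prefix="S"):
    """GenotypeMatrix from a plain (n_samples, n_snps) array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    snps = [
        SnpRecord(snp_id=f"snp{j + 1}", chrom=chrom, pos=start + j * step) for j in range(m)
    ]
    return GenotypeMatrix(
        sample_ids=[f"{sample_prefix}{i + 1}" for i in range(n)], snps=snps, dosages=dosages
    )


def make_covariates(n, rng, params=None):
    return synthetic.simulate_covariates(n, params or synthetic.CovariateParams(), rng)


@pytest.fixture
def small_covariates(rng):
    return make_covariates(60, rng)


@pytest.fixture(scope="session")
def small_study():
    """A tiny 3-cohort study with two planted eQTLs, reused across tests."""
    config = synthetic.SimulationConfig(
        seed=2024,
        cohort_sizes=(200, 160, 180),
        cohort_names=("disc", "repA", "repB"),
        n_blocks=4,
        snps_per_block=10,
        haplotypes_per_block=4,
        n_probesets=8,
        n_genes=4,
        planted_eqtls=(
            synthetic.PlantedEqtl(snp_index=5, probeset_index=0, h2=0.5, direction=-1),
            synthetic.PlantedEqtl(snp_index=22, probeset_index=3, h2=0.3, direction=1),
        ),
        outlier_fraction=0.01,
    )
    return synthetic.simulate_study(config)
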