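import pytest
from hypothesis import settings

from ssphase.model import GraphPhasingModel, RunConfig
from ssphase.simulate import SimConfig, simulate

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_bundle():
    """Clean small genome: 4 diploid chromosomes + X/Y, 40 libraries, no noise."""
    cfg = SimConfig(
        n_diploid_chroms=4,
        chrom_lengths=[100_000_000] * 4,
        haploid_chroms=[60_000_000, 30_000_000],
        unitigs_per_chrom=8,
        n_libraries=40,
        seed=11,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_fit(small_bundle):
    model = GraphPhasingModel(
        small_bundle.graph,
        small_bundle.counts_all,
        small_bundle.counts_hap,
        RunConfig(),
    )
    return model.fit()
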