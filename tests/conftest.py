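import pytest

from scdnasim import (
    SimulationParams,
    generate_synthetic_dbsnp,
    generate_synthetic_reference,
    validate_params,
)


@pytest.fixture(scope="session")
def genome_200k():
    return generate_synthetic_reference(1, 200_000, gc=0.5, seed=11)


@pytest.fixture(scope="session")
def genome_2mb():
    return generate_synthetic_reference(1, 2_000_000, gc=0.5, seed=11)


@pytest.fixture(scope="session")
def dbsnp_200k(genome_200k):
    return generate_synthetic_dbsnp(genome_200k, 5000, seed=12)


@pytest.fixture
def make_params():
    def factory(**kwargs):
        # point-variant tests often use tiny batches; keep the CNV cluster
        # feasibility invariant trivially satisfiable unless a test sets it
        kwargs.setdefault("cluster_no", 1)
        kwargs.setdefault("normal_frac", 0.0)
        return validate_params(SimulationParams(**kwargs))

    return factory
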