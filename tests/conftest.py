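import numpy as np
import pytest

from rtetx.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic dataset (master seed 0), shared across tests."""
    return simulate_dataset(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def bundle(dataset):
    return dataset.bundle()


@pytest.fixture(scope="session")
def written_dataset(dataset, tmp_path_factory):
    from rtetx.simulate import write_dataset

    outdir = tmp_path_factory.mktemp("data")
    manifest = write_dataset(dataset, outdir)
    return outdir, manifest


def per_base_overlap(iv_a, iv_b) -> int:
    """Brute-force shared-base count between two half-open intervals."""
    if iv_a.chrom != iv_b.chrom:
        return 0
    return len(
        set(range(iv_a.start, iv_a.end)) & set(range(iv_b.start, iv_b.end))
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
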