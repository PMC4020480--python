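import numpy as np
import pytest

from apatrend.simdata import SimConfig, Reference, SimReads, make_reference, simulate_reads


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(n_genes=80, depth=40_000, seed=101)


@pytest.fixture(scope="session")
def reference(sim_config) -> Reference:
    return make_reference(sim_config)


@pytest.fixture(scope="session")
def sim_reads(reference, sim_config) -> SimReads:
    return simulate_reads(reference, sim_config)


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory, reference, sim_reads):
    """The synthetic dataset written to disk once per session."""
    from apatrend.simdata import write_dataset

    outdir = tmp_path_factory.mktemp("dataset")
    paths = write_dataset(reference, sim_reads, outdir)
    return outdir, paths


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
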