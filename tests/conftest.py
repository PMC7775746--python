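import numpy as np
import pytest

from chromact import SimulationConfig, simulate_study
from chromact.pipeline import RunConfig, run


def tiny_config(seed: int = 3) -> SimulationConfig:
    """Miniature study used by fast end-to-end tests."""
    return SimulationConfig(
        seed=seed,
        n_chroms=2,
        chrom_length=600_000,
        n_genes=40,
        site_free_chroms=1,
        n_sites={"promoter": 8, "enhancer": 10, "repressed": 3, "null": 5},
        n_background_regions={
            "promoter": 8, "enhancer": 8, "repressed": 4, "uncharacterized": 8,
        },
    )


@pytest.fixture(scope="session")
def tiny_study():
    return simulate_study(tiny_config())


@pytest.fixture(scope="session")
def full_run():
    """One default-scale pipeline run shared by the recovery tests."""
    return run(RunConfig(seed=11), "all", write_outputs=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
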