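import pytest

from apaqtl import pipeline as pl
from apaqtl import simulate as sim


@pytest.fixture(scope="session")
def small_config():
    return sim.SyntheticConfig(n_genes=40, n_individuals=10, seed=1)


@pytest.fixture(scope="session")
def small_study(small_config):
    """A compact but complete two-fraction study with ground truth."""
    truth = sim.generate_truth(small_config)
    geno = sim.generate_genotypes(truth, small_config)
    read_set, sheet = sim.simulate_dataset(truth, geno, small_config)
    return dict(config=small_config, truth=truth, genotypes=geno,
                read_set=read_set, sample_sheet=sheet)


@pytest.fixture(scope="session")
def small_discovery(small_study):
    """PAS discovery run on the compact study."""
    s = small_study
    return pl.run_pas_discovery(
        s["read_set"], s["truth"].genome, s["truth"].annotation_frame(), s["sample_sheet"]
    )
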