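import numpy as np
import pytest

from regarch import compartments as comp
from regarch.synthdata import SimConfig, gen_compartment_dataset


@pytest.fixture(scope="session")
def comp_dataset():
    """Reference compartment simulation (seed 7, delta 0.3)."""
    return gen_compartment_dataset(SimConfig(seed=7))


@pytest.fixture(scope="session")
def comp_calls(comp_dataset):
    """Aggregated, oriented calls for the reference simulation."""
    binmat = comp.aggregate_probes_to_bins(
        comp_dataset.beta, comp_dataset.probes, comp_dataset.bins, min_probes=3)
    return comp.orient_and_call(binmat, comp_dataset.reference)


@pytest.fixture(scope="session")
def comp_results(comp_dataset, comp_calls):
    return comp.test_bins(comp_calls, comp_dataset.strata)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
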