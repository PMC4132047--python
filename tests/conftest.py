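import numpy as np
import pytest

from silkfric import bond_model, extract, structures, synth


@pytest.fixture(scope="session")
def small_spec():
    """Reduced composite: one 2x2 crystal unit, two 3-chain bundles of a
    12-residue sequence - big enough for a real interface, small enough for
    fast SASA."""
    return structures.BuilderSpec(
        n_units=1, strands_per_sheet=2, sheets_per_unit=2, polyala_length=8,
        n_bundles=2, chains_per_bundle=3,
        amorphous_sequence="GPGGYGPGSQGP")


@pytest.fixture(scope="session")
def small_composite(small_spec):
    return structures.assemble_composite(small_spec)


@pytest.fixture(scope="session")
def truth():
    return synth.GroundTruth()


@pytest.fixture(scope="session")
def dataset(truth):
    """One full synthetic campaign (7 velocities x 4 replicas x 2 kinds)
    aggregated to a friction dataset; shared across tests."""
    traces = synth.generate_dataset(seed=42, truth=truth)
    ds = extract.aggregate(traces, truth.N, truth.N_total)
    return traces, ds


@pytest.fixture(scope="session")
def best_fit_params():
    """Best-fit parameter point: U_bond = 8.4 kT, ma = 1.32 nm."""
    return bond_model.BondModelParams(a=1.32, m=1.0, U_bond=8.4)
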