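import numpy as np
import pytest

from diazoquant import (
    SampleSpec,
    SyntheticTruth,
    TaxonSpec,
    default_truth,
    synthetic_catalog,
)


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def catalog(truth):
    return synthetic_catalog(truth, seed=11)


@pytest.fixture()
def sample_spec():
    return SampleSpec(
        sample_id="S1",
        V_seawater=100.0,
        Vi=1e-3,
        total_reads=20_000,
        read_length=100,
        seed=42,
    )


@pytest.fixture(scope="session")
def five_taxa_truth():
    """Five equally-dense diazotroph taxa, markers only (no bulk reads)."""
    return SyntheticTruth(
        taxa=tuple(
            TaxonSpec(f"taxon_{k}", "cyanobacteria", 1.0e5, 1.0, 400) for k in range(5)
        ),
        background_bacteria_density=0.0,
        outgroup_read_fraction=0.0,
        unassigned_read_fraction=0.0,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
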