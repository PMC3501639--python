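import numpy as np
import pytest

from icefloe import AlignedSampleSet, DemographicScenario, MutationModel, SamplingEvent


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def toy_sets():
    """Two small populations fixed for partially distinct haplotypes."""
    a = AlignedSampleSet(
        set_id="A",
        ids=["a1", "a2", "a3"],
        seqs=["AATGC", "AATGC", "AATGA"],
    )
    b = AlignedSampleSet(
        set_id="B",
        ids=["b1", "b2", "b3"],
        seqs=["AATGA", "ACTGA", "ACTGA"],
    )
    return a, b


@pytest.fixture
def single_deme_scenario():
    """Neutral single-deme scenario with a homogeneous mutation clock."""
    return DemographicScenario(
        demes={"A": 1000.0},
        sampling_events=[SamplingEvent("A", 10)],
        mutation=MutationModel(rate_per_site_per_my=0.04, gamma_shape=None),
        sequence_length=370,
    )

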