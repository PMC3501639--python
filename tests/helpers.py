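"""Shared scenario builders for the test suite."""

from icefloe import DemographicScenario, MutationModel, SamplingEvent


def two_deme_scenario(m, n_per_deme=16, N=1000.0, rate=0.06):
    """Symmetric two-deme island scenario used across tests."""
    return DemographicScenario(
        demes={"A": N, "B": N},
        sampling_events=[SamplingEvent("A", n_per_deme), SamplingEvent("B", n_per_deme)],
        migration={"A": {"B": m}, "B": {"A": m}},
        mutation=MutationModel(rate_per_site_per_my=rate, gamma_shape=None),
        sequence_length=370,
        label=f"island_m{m:g}",
    )
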