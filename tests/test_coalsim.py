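import numpy as np
import pytest
from scipy import stats

from icefloe import (
    DemographicScenario,
    HistoricalEvent,
    MutationModel,
    SamplingEvent,
    census_to_female_ne,
    simulate_dataset,
    simulate_genealogy,
)
from icefloe.coalsim import (
    SimulationError,
    hky_rate_matrix,
    rate_per_generation,
    replicate_rng,
)
from icefloe.differentiation import distance_matrix
from icefloe.popgen import harmonic_number
from helpers import two_deme_scenario


class TestCensusConversion:
    def test_stated_ratios(self):
        # 1:1 sex ratio, 1.5:1 total:adult, Ne/N = 0.5 -> N/6
        assert census_to_female_ne(12_000) == 2_000

    def test_smallest_representable(self):
        assert census_to_female_ne(6) == 1

    def test_too_small_errors(self):
        with pytest.raises(ValueError):
            census_to_female_ne(2)

    def test_nonpositive_errors(self):
        with pytest.raises(ValueError):
            census_to_female_ne(0)


class TestGenealogy:
    def test_pairwise_tmrca_expectation(self, rng):
        # haploid coalescent: E[T2] = N generations
        sc = DemographicScenario(
            demes={"A": 1000.0}, sampling_events=[SamplingEvent("A", 2)]
        )
        t = [simulate_genealogy(sc, rng).tmrca() for _ in range(20_000)]
        assert np.mean(t) == pytest.approx(1000.0, rel=0.02)

    def test_total_branch_length_expectation(self, rng):
        # E[L] = 2N * sum_{i=1}^{n-1} 1/i for a constant-size deme
        n, N = 8, 500.0
        sc = DemographicScenario(
            demes={"A": N}, sampling_events=[SamplingEvent("A", n)]
        )
        L = [simulate_genealogy(sc, rng).total_branch_length()
             for _ in range(8_000)]
        assert np.mean(L) == pytest.approx(2 * N * harmonic_number(n - 1), rel=0.03)

    def test_ancient_tip_sits_at_its_age(self, rng):
        sc = DemographicScenario(
            demes={"A": 500.0},
            sampling_events=[SamplingEvent("A", 3),
                             SamplingEvent("A", 2, age_generations=12.5)],
        )
        g = simulate_genealogy(sc, rng)
        assert np.all(g.time[:3] == 0.0)
        assert np.all(g.time[3:5] == 12.5)
        assert g.tmrca() > 12.5

    def test_disconnected_demes_error(self, rng):
        sc = DemographicScenario(
            demes={"A": 100.0, "B": 100.0},
            sampling_events=[SamplingEvent("A", 2), SamplingEvent("B", 2)],
        )
        with pytest.raises(SimulationError):
            simulate_genealogy(sc, rng)

    def test_divergence_event_connects_demes(self, rng):
        sc = DemographicScenario(
            demes={"A": 100.0, "B": 100.0},
            sampling_events=[SamplingEvent("A", 2), SamplingEvent("B", 2)],
            historical_events=[HistoricalEvent(time=50.0, kind="move_lineages",
                                               source="B", sink="A")],
        )
        g = simulate_genealogy(sc, rng)
        assert g.tmrca() > 50.0

    def test_bottleneck_shortens_post_event_coalescence(self, rng):
        # a size crash deep in the past accelerates coalescence beyond it
        base = dict(demes={"A": 5000.0},
                    sampling_events=[SamplingEvent("A", 6)])
        plain = DemographicScenario(**base)
        crash = DemographicScenario(
            **base,
            historical_events=[HistoricalEvent(time=100.0, kind="size_change",
                                               deme="A", new_size=50.0)],
        )
        t_plain = np.mean([simulate_genealogy(plain, rng).tmrca()
                           for _ in range(2_000)])
        t_crash = np.mean([simulate_genealogy(crash, rng).tmrca()
                           for _ in range(2_000)])
        assert t_crash < 0.25 * t_plain

    def test_matches_msprime_tmrca_distribution(self, rng):
        msprime = pytest.importorskip("msprime")
        N, n, reps = 800.0, 5, 1_500
        sc = DemographicScenario(
            demes={"A": N}, sampling_events=[SamplingEvent("A", n)]
        )
        ours = [simulate_genealogy(sc, rng).tmrca() for _ in range(reps)]
        theirs = [
            ts.max_root_time
            for ts in msprime.sim_ancestry(
                samples=n, ploidy=1, population_size=N,
                num_replicates=reps, random_seed=97,
            )
        ]
        assert stats.ks_2samp(ours, theirs).pvalue > 0.01

    def test_newick_export_parses(self, rng):
        dendropy = pytest.importorskip("dendropy")
        sc = DemographicScenario(
            demes={"A": 200.0}, sampling_events=[SamplingEvent("A", 4)]
        )
        nwk = simulate_genealogy(sc, rng).to_newick()
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert len(tree.leaf_nodes()) == 4


class TestMutation:
    def test_zero_rate_gives_identical_sequences(self, rng):
        sc = DemographicScenario(
            demes={"A": 300.0},
            sampling_events=[SamplingEvent("A", 6)],
            mutation=MutationModel(rate_per_site_per_my=1e-30),
            sequence_length=100,
        )
        st = simulate_dataset(sc, rng)["A"]
        assert len(set(st.seqs)) == 1

    def test_seeded_reproducibility(self):
        sc = two_deme_scenario(0.05, n_per_deme=5)
        a = simulate_dataset(sc, replicate_rng(123, 0))
        b = simulate_dataset(sc, replicate_rng(123, 0))
        assert a["A"].seqs == b["A"].seqs and a["B"].seqs == b["B"].seqs
        c = simulate_dataset(sc, replicate_rng(123, 1))
        assert a["A"].seqs != c["A"].seqs

    def test_hky_matrix_properties(self):
        Q = hky_rate_matrix(4.0, (0.3, 0.2, 0.2, 0.3))
        pi = np.array([0.3, 0.2, 0.2, 0.3])
        assert np.allclose(Q.sum(axis=1), 0.0)
        assert np.allclose(pi @ Q, 0.0, atol=1e-12)  # stationarity
        assert -np.dot(pi, np.diag(Q)) == pytest.approx(1.0)  # unit mean rate

    def test_long_branch_divergence_matches_jc(self, rng):
        # kappa=1, equal frequencies reduce HKY to JC: expected proportion of
        # differing sites between two tips at distance d is (3/4)(1-e^{-4d/3})
        N, mu = 200.0, 5e-4  # E[2*T2*mu] = 0.2 subs/site: real saturation
        sc = DemographicScenario(
            demes={"A": N},
            sampling_events=[SamplingEvent("A", 2)],
            mutation=MutationModel(kappa=1.0, gamma_shape=None,
                                   rate_per_site_per_my=mu * 1e6 / 52),
            sequence_length=2_000,
        )
        ratios = []
        for _ in range(300):
            g = simulate_genealogy(sc, rng)
            d = 2 * g.tmrca() * mu
            from icefloe.coalsim import apply_mutations
            sets = apply_mutations(g, sc.mutation, sc.sequence_length, mu, rng)
            st = sets["A"]
            p_obs = distance_matrix([st], metric="raw-p").matrix[0, 1]
            p_exp = 0.75 * (1 - np.exp(-4 * d / 3))
            ratios.append((p_obs, p_exp))
        obs, exp = np.array(ratios).T
        assert np.mean(obs) == pytest.approx(np.mean(exp), rel=0.03)

    def test_base_composition_follows_stationary_frequencies(self, rng):
        freqs = (0.4, 0.1, 0.2, 0.3)
        sc = DemographicScenario(
            demes={"A": 500.0},
            sampling_events=[SamplingEvent("A", 10)],
            mutation=MutationModel(base_freqs=freqs, gamma_shape=None,
                                   rate_per_site_per_my=0.05),
            sequence_length=3_000,
        )
        st = simulate_dataset(sc, rng)["A"]
        enc = st.encoded()
        counts = np.bincount(enc.ravel(), minlength=4)[:4]
        assert np.allclose(counts / counts.sum(), freqs, atol=0.03)


class TestDatasetSimulation:
    def test_sampling_template_sizes_and_ages(self, rng):
        sc = DemographicScenario(
            demes={"X": 400.0},
            sampling_events=[
                SamplingEvent("X", 9, age_generations=12.5, label="PRI"),
                SamplingEvent("X", 44, label="HBFB"),
                SamplingEvent("X", 22, label="BBDS"),
            ],
            mutation=MutationModel(rate_per_site_per_my=0.04),
        )
        sets = simulate_dataset(sc, rng)
        assert {k: v.n for k, v in sets.items()} == {"PRI": 9, "HBFB": 44,
                                                     "BBDS": 22}
        assert np.all(sets["PRI"].ages == 12.5)
        assert np.all(sets["HBFB"].ages == 0.0)

    def test_mutation_rate_prior_is_uniform(self, rng):
        lo, hi = 0.02, 0.063
        model = MutationModel(rate_per_site_per_my=(lo, hi))
        draws = np.array([model.draw_rate(rng) for _ in range(2_000)])
        assert stats.kstest(draws, stats.uniform(lo, hi - lo).cdf).pvalue > 0.01

    def test_rate_unit_conversion(self):
        # 2% per my at 52 y/generation -> 1.04e-6 per site per generation
        assert rate_per_generation(0.02, 52.0) == pytest.approx(1.04e-6)


def test_island_model_phi_st_decreases_with_migration(rng):
    from icefloe.differentiation import pairwise_phi_st

    medians = []
    for m in (0.001, 0.01, 0.1):
        sc = two_deme_scenario(m, n_per_deme=12, N=800.0)
        phis = []
        for r in range(120):
            sets = simulate_dataset(sc, rng)
            phis.append(pairwise_phi_st(sets["A"], sets["B"]))
        medians.append(np.median(phis))
    assert medians[0] > medians[1] > medians[2]
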