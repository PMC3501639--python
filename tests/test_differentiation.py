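import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icefloe import AlignedSampleSet
from icefloe.differentiation import (
    amova,
    comparison_matrix,
    distance_matrix,
    fdr_correct,
    frequency_f_st,
    jukes_cantor,
    pairwise_comparisons,
    pairwise_phi_st,
    permutation_test,
)

# ---------------------------------------------------------------------------
# brute-force AMOVA oracle: plain double loops, no shared code with the
# package implementation


def brute_force_amova_2level(d, labels):
    labels = list(labels)
    N = len(labels)
    pops = sorted(set(labels), key=labels.index)
    P = len(pops)
    ssd_total = 0.0
    for i in range(N):
        for j in range(N):
            ssd_total += d[i][j] ** 2
    ssd_total /= 2.0 * N
    ssd_wp = 0.0
    for p in pops:
        idx = [i for i in range(N) if labels[i] == p]
        s = 0.0
        for i in idx:
            for j in idx:
                s += d[i][j] ** 2
        ssd_wp += s / (2.0 * len(idx))
    ssd_ap = ssd_total - ssd_wp
    ms_wp = ssd_wp / (N - P)
    ms_ap = ssd_ap / (P - 1)
    sum_n2 = sum(labels.count(p) ** 2 for p in pops)
    n_prime = (N - sum_n2 / N) / (P - 1)
    sigma_w = ms_wp
    sigma_a = (ms_ap - ms_wp) / n_prime
    tot = sigma_a + sigma_w
    phi = sigma_a / tot if tot > 0 else 0.0
    return sigma_a, sigma_w, phi


def brute_force_amova_3level(d, labels, groups):
    labels = list(labels)
    N = len(labels)
    pops = sorted(set(labels), key=labels.index)
    P, G = len(pops), len(groups)
    pop_group = {p: g for g, ps in groups.items() for p in ps}

    def block_ssd(idx):
        s = 0.0
        for i in idx:
            for j in idx:
                s += d[i][j] ** 2
        return s / (2.0 * len(idx))

    ssd_total = block_ssd(range(N))
    ssd_wp = sum(block_ssd([i for i in range(N) if labels[i] == p]) for p in pops)
    ssd_wg = sum(
        block_ssd([i for i in range(N) if pop_group[labels[i]] == g])
        for g in groups
    )
    ms_wp = ssd_wp / (N - P)
    ms_ap = (ssd_wg - ssd_wp) / (P - G)
    ms_ag = (ssd_total - ssd_wg) / (G - 1)
    sizes = {p: labels.count(p) for p in pops}
    Ng = {g: sum(sizes[p] for p in groups[g]) for g in groups}
    sum_n2_over_Ng = sum(
        sum(sizes[p] ** 2 for p in groups[g]) / Ng[g] for g in groups
    )
    n1 = (N - sum_n2_over_Ng) / (P - G)
    n2 = (sum_n2_over_Ng - sum(sizes[p] ** 2 for p in pops) / N) / (G - 1)
    n3 = (N - sum(Ng[g] ** 2 for g in groups) / N) / (G - 1)
    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n1
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
    return sigma_a, sigma_b, sigma_c


def random_instance(rng, n_pops=None, three_level=False):
    n_pops = n_pops or int(rng.integers(2, 4))
    sizes = rng.integers(2, 5, size=n_pops)
    N = int(sizes.sum())
    while N > 12:
        sizes[np.argmax(sizes)] -= 1
        N = int(sizes.sum())
    labels = np.repeat([f"p{k}" for k in range(n_pops)], sizes)
    pts = rng.normal(size=(N, 3))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    groups = None
    if three_level and n_pops >= 3:
        names = [f"p{k}" for k in range(n_pops)]
        groups = {"g1": names[:1], "g2": names[1:]}
    return d, labels, groups


class TestJukesCantor:
    def test_zero(self):
        assert jukes_cantor(0.0) == 0.0

    def test_closed_form_value(self):
        assert jukes_cantor(0.05) == pytest.approx(
            -0.75 * math.log(1 - 4 * 0.05 / 3), abs=1e-12
        )
        assert jukes_cantor(0.05) == pytest.approx(0.05174, abs=5e-5)

    def test_domain_edge(self):
        with pytest.raises(ValueError):
            jukes_cantor(0.75)

    @given(st.floats(0.0, 0.74))
    @settings(max_examples=100, deadline=None)
    def test_correction_never_shrinks(self, p):
        assert jukes_cantor(p) >= p - 1e-12


class TestAmova:
    def test_identical_sequences_zero_everywhere(self):
        a = AlignedSampleSet("A", ["a1", "a2"], ["AATT", "AATT"])
        b = AlignedSampleSet("B", ["b1", "b2"], ["AATT", "AATT"])
        dm = distance_matrix([a, b])
        res = amova(dm, ["A", "A", "B", "B"])
        assert res.phi_st == 0.0
        assert all(v == 0.0 for v in res.sigma2.values())

    def test_fixed_differences_give_one(self):
        a = AlignedSampleSet("A", ["a1", "a2"], ["AAAA", "AAAA"])
        b = AlignedSampleSet("B", ["b1", "b2"], ["TTTT", "TTTT"])
        assert pairwise_phi_st(a, b, metric="raw-p") == pytest.approx(1.0)

    def test_singleton_population_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError, match="merge"):
            amova(d, ["A", "A", "B"])

    def test_matches_brute_force_oracle_2level(self, rng):
        for _ in range(200):
            d, labels, _ = random_instance(rng)
            res = amova(d, labels)
            sa, sw, phi = brute_force_amova_2level(d, labels)
            assert res.sigma2["among_populations"] == pytest.approx(sa, abs=1e-10)
            assert res.sigma2["within_populations"] == pytest.approx(sw, abs=1e-10)
            assert res.phi_st == pytest.approx(phi, abs=1e-10)

    def test_matches_brute_force_oracle_3level(self, rng):
        checked = 0
        while checked < 100:
            d, labels, groups = random_instance(rng, n_pops=3, three_level=True)
            if groups is None:
                continue
            res = amova(d, labels, groups=groups)
            sa, sb, sc = brute_force_amova_3level(d, labels, groups)
            assert res.sigma2["among_groups"] == pytest.approx(sa, abs=1e-10)
            assert res.sigma2["among_populations"] == pytest.approx(sb, abs=1e-10)
            assert res.sigma2["within_populations"] == pytest.approx(sc, abs=1e-10)
            checked += 1

    def test_percentages_sum_to_100(self, rng):
        d, labels, _ = random_instance(rng)
        res = amova(d, labels)
        assert sum(res.pct.values()) == pytest.approx(100.0)

    def test_df_sum_is_n_minus_1(self, rng):
        d, labels, groups = random_instance(rng, n_pops=3, three_level=True)
        res = amova(d, labels, groups=groups)
        assert sum(res.df.values()) == len(labels) - 1


class TestPhiStInvariances:
    def test_relabeling_within_population_invariant(self, rng):
        d, labels, _ = random_instance(rng, n_pops=2)
        res1 = amova(d, labels)
        # permute individuals within each population
        perm = np.arange(len(labels))
        for p in set(labels):
            idx = np.flatnonzero(labels == p)
            perm[idx] = rng.permutation(idx)
        res2 = amova(d[np.ix_(perm, perm)], labels[perm])
        assert res1.phi_st == pytest.approx(res2.phi_st, abs=1e-12)

    def test_identical_composition_near_zero(self):
        h1, h2 = "A" * 20, "A" * 18 + "CT"
        seqs = [h1, h2, h1, h2]
        a = AlignedSampleSet("A", ["a1", "a2", "a3", "a4"], seqs)
        b = AlignedSampleSet("B", ["b1", "b2", "b3", "b4"], seqs)
        phi = pairwise_phi_st(a, b)
        assert phi < 0.0  # expectation 0, small negative from the correction

    def test_negative_values_not_clipped(self):
        h1, h2 = "A" * 20, "A" * 18 + "CT"
        a = AlignedSampleSet("A", ["a1", "a2"], [h1, h2])
        b = AlignedSampleSet("B", ["b1", "b2"], [h1, h2])
        assert pairwise_phi_st(a, b) < 0.0


class TestFrequencyFst:
    def test_identical_frequency_vectors_nonpositive(self):
        seqs = ["AAAA", "TTTT", "TTTT"]
        a = AlignedSampleSet("A", ["a1", "a2", "a3"], seqs)
        b = AlignedSampleSet("B", ["b1", "b2", "b3"], seqs)
        assert frequency_f_st(a, b) <= 0.0

    def test_disjoint_monomorphic_sets(self):
        a = AlignedSampleSet("A", ["a1", "a2"], ["AAAA", "AAAA"])
        b = AlignedSampleSet("B", ["b1", "b2"], ["TTTT", "TTTT"])
        assert frequency_f_st(a, b) == pytest.approx(1.0)

    def test_matches_amova_with_identity_distance(self, toy_sets):
        a, b = toy_sets
        dm = distance_matrix([a, b], metric="haplotype-identity")
        labels = ["A"] * a.n + ["B"] * b.n
        assert frequency_f_st(a, b) == pytest.approx(
            amova(dm, labels).phi_st, abs=1e-12
        )


class TestPermutationTest:
    def test_extreme_observed_gives_minimal_p(self):
        h1, h2 = "A" * 20, "A" * 16 + "CTCT"
        a = AlignedSampleSet("A", [f"a{i}" for i in range(12)], [h1] * 12)
        b = AlignedSampleSet("B", [f"b{i}" for i in range(12)], [h2] * 12)
        _, p = permutation_test(a, b, n_perm=200, seed=0)
        assert p == pytest.approx(1 / 201)

    def test_deterministic_under_seed(self, toy_sets):
        a, b = toy_sets
        r1 = permutation_test(a, b, n_perm=200, seed=11)
        r2 = permutation_test(a, b, n_perm=200, seed=11)
        assert r1 == r2

    def test_p_value_in_unit_interval(self, toy_sets):
        a, b = toy_sets
        _, p = permutation_test(a, b, n_perm=150, seed=3)
        assert 0 < p <= 1

    def test_requires_enough_permutations(self, toy_sets):
        a, b = toy_sets
        with pytest.raises(ValueError):
            permutation_test(a, b, n_perm=50)


class TestFdrCorrect:
    def test_all_tiny_p_all_significant(self):
        flags = fdr_correct([0.001] * 15, q=0.05)
        assert flags.all()

    def test_bh_step_up_hand_example(self):
        # thresholds k*q/m = 0.0125, 0.025, 0.0375, 0.05; step-up stops at
        # rank 2 (0.04 > 0.0375), so ranks 1-2 are significant
        flags = fdr_correct([0.01, 0.02, 0.04, 0.9], q=0.05)
        assert flags.tolist() == [True, True, False, False]
        # moving rank 3 under its threshold pulls it in
        flags = fdr_correct([0.01, 0.02, 0.037, 0.9], q=0.05)
        assert flags.tolist() == [True, True, True, False]

    def test_all_ones_none_significant(self):
        assert not fdr_correct([1.0, 1.0, 1.0]).any()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([])


def test_comparison_matrix_layout(toy_sets):
    a, b = toy_sets
    results = pairwise_comparisons([a, b], n_perm=150, seed=2)
    m = comparison_matrix(results, ["A", "B"])
    # Phi_ST below the diagonal, frequency F_ST above
    assert m.loc["B", "A"] == pytest.approx(results[0].phi_st, abs=1e-3)
    assert m.loc["A", "B"] == pytest.approx(results[0].f_st, abs=1e-3)
    assert m.loc["A", "A"] == 0.0
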