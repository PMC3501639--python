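"""Per-sample-set diversity statistics.

Implements the standard mtDNA control-region summary panel: segregating
sites S, haplotype count H, Nei's unbiased haplotype diversity Hd, private
haplotype count U, per-site nucleotide diversity pi, and Watterson's
theta(S), plus a coalescent-resampling confidence interval for Hd.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import AlignedSampleSet, HaplotypeTable, collapse_haplotypes


@dataclass
class DiversitySummary:
    set_id: str
    n: int
    S: int
    H: int
    Hd: float
    U: int | None
    pi: float
    theta_S: float
    hd_ci: tuple[float, float] | None = None


def _retained(enc: np.ndarray, site_policy: str) -> np.ndarray:
    """Columns used for within-set statistics under the site policy."""
    if site_policy == "complete":
        keep = ~np.any(enc >= 4, axis=0)
        return enc[:, keep]
    if site_policy == "all":
        return enc
    raise ValueError(f"unknown site_policy {site_policy!r}")


def segregating_sites(sample_set: AlignedSampleSet, site_policy: str = "complete") -> int:
    """Number of retained columns with at least two observed bases."""
    if sample_set.n < 2:
        raise ValueError("segregating sites require at least 2 sequences")
    enc = _retained(sample_set.encoded(), site_policy)
    S = 0
    for col in enc.T:
        bases = np.unique(col[col < 4])
        if len(bases) >= 2:
            S += 1
    return S


def haplotype_diversity(counts) -> float:
    """Nei's unbiased haplotype diversity, Hd = n(1 - sum p_i^2)/(n - 1)."""
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    n = c.sum()
    if n < 2:
        raise ValueError("haplotype diversity requires n >= 2")
    p = c / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def nucleotide_diversity(
    sample_set: AlignedSampleSet, site_policy: str = "complete", per_site: bool = True
) -> float:
    """Mean pairwise proportion (or count) of differing retained sites.

    Uncorrected distances averaged over all n(n-1)/2 sequence pairs.
    """
    if sample_set.n < 2:
        raise ValueError("nucleotide diversity requires at least 2 sequences")
    enc = _retained(sample_set.encoded(), site_policy)
    n, L = enc.shape
    if L == 0:
        raise ValueError("no sites retained")
    # pairwise difference counts via per-base indicator matmuls
    diffs = np.zeros((n, n))
    valid = (enc < 4).astype(np.float64)
    vv = valid @ valid.T
    match = np.zeros((n, n))
    for b in range(4):
        X = (enc == b).astype(np.float64)
        match += X @ X.T
    diffs = vv - match
    iu = np.triu_indices(n, k=1)
    if per_site:
        with np.errstate(invalid="ignore"):
            per_pair = diffs[iu] / vv[iu]
        return float(np.nanmean(per_pair))
    return float(diffs[iu].mean())


def harmonic_number(n: int) -> float:
    """a_n = sum_{i=1}^{n} 1/i."""
    return float(np.sum(1.0 / np.arange(1, n + 1)))


def watterson_theta(S: int, n: int, length: int | None = None) -> float:
    """Watterson's estimator theta = S / a_{n-1}; per-locus scale.

    Pass ``length`` to get the per-site scale instead.
    """
    if n < 2:
        raise ValueError("Watterson's theta requires n >= 2")
    theta = S / harmonic_number(n - 1)
    if length is not None:
        theta /= length
    return float(theta)


def private_haplotypes(table: HaplotypeTable, set_id: str) -> int:
    """Haplotypes observed only in ``set_id`` (Table-style U column)."""
    if set_id not in table.set_ids:
        raise KeyError(f"unknown sample set {set_id!r}")
    if len(table.set_ids) < 2:
        warnings.warn("single-set table: every haplotype is trivially private")
        return int((table.column(set_id) > 0).sum())
    col = table.column(set_id)
    others = table.counts.sum(axis=1) - col
    return int(np.sum((col > 0) & (others == 0)))


def singleton_haplotypes(table: HaplotypeTable) -> int:
    """Haplotypes with total count 1 across the full dataset."""
    return int(np.sum(table.counts.sum(axis=1) == 1))


def _simulate_hd(n: int, theta_locus: float, rng: np.random.Generator) -> float:
    """One neutral-coalescent replicate of Hd for sample size n and theta.

    Infinite-sites genealogy in coalescent time units: inter-coalescent
    times ~ Exp(k(k-1)/2); mutations Poisson(theta/2 * total length) dropped
    uniformly on branches; haplotype = the set of mutations above a tip.
    """
    # Kingman topology via sequential random merging, tracking tip membership
    lineages = [frozenset([i]) for i in range(n)]
    mut_sets: list[set[int]] = [set() for _ in range(n)]
    k = n
    branch_owners: list[frozenset] = []
    branch_lengths: list[float] = []
    active = {fs: 0.0 for fs in lineages}
    while k > 1:
        t = rng.exponential(2.0 / (k * (k - 1)))
        for fs in active:
            active[fs] += t
        i, j = rng.choice(k, size=2, replace=False)
        keys = list(active.keys())
        a, b = keys[i], keys[j]
        branch_owners.append(a)
        branch_lengths.append(active.pop(a))
        branch_owners.append(b)
        branch_lengths.append(active.pop(b))
        active[a | b] = 0.0
        k -= 1
    total = float(np.sum(branch_lengths))
    n_mut = rng.poisson(theta_locus / 2.0 * total)
    if n_mut and total > 0:
        probs = np.asarray(branch_lengths) / total
        placement = rng.choice(len(branch_owners), size=n_mut, p=probs)
        for m, bi in enumerate(placement):
            for tip in branch_owners[bi]:
                mut_sets[tip].add(m)
    haps: dict[frozenset, int] = {}
    for s in mut_sets:
        key = frozenset(s)
        haps[key] = haps.get(key, 0) + 1
    return haplotype_diversity(list(haps.values()))


def hd_confidence_interval(
    sample_set: AlignedSampleSet,
    reps: int = 1000,
    seed: int | None = None,
    site_policy: str = "complete",
) -> tuple[float, float]:
    """95% interval for Hd from neutral-coalescent resimulation.

    Conditions on the set's sample size and its Watterson theta (per locus);
    the empirical 2.5/97.5 percentiles of simulated Hd form the interval.
    This reconstructs the DnaSP-style coalescent interval rather than
    re-implementing that program.
    """
    if reps < 1000:
        raise ValueError("use at least 1000 replicates")
    S = segregating_sites(sample_set, site_policy)
    theta = watterson_theta(S, sample_set.n)
    rng = np.random.default_rng(seed)
    sims = np.array([_simulate_hd(sample_set.n, theta, rng) for _ in range(reps)])
    lo, hi = np.percentile(sims, [2.5, 97.5])
    return float(lo), float(hi)


def diversity_summary(
    sample_set: AlignedSampleSet,
    table: HaplotypeTable | None = None,
    site_policy: str = "complete",
    hd_ci_reps: int = 0,
    seed: int | None = None,
) -> DiversitySummary:
    """Full per-set diversity panel (N, S, H, Hd, U, pi, theta(S))."""
    S = segregating_sites(sample_set, site_policy)
    own = collapse_haplotypes([sample_set], site_policy=site_policy)
    counts = own.counts[:, 0]
    ci = None
    if hd_ci_reps:
        ci = hd_confidence_interval(sample_set, reps=hd_ci_reps, seed=seed,
                                    site_policy=site_policy)
    U = private_haplotypes(table, sample_set.set_id) if table is not None else None
    return DiversitySummary(
        set_id=sample_set.set_id,
        n=sample_set.n,
        S=S,
        H=int(len(counts)),
        Hd=haplotype_diversity(counts),
        U=U,
        pi=nucleotide_diversity(sample_set, site_policy),
        theta_S=watterson_theta(S, sample_set.n),
        hd_ci=ci,
    )


def diversity_table(
    sets: list[AlignedSampleSet], site_policy: str = "complete"
) -> pd.DataFrame:
    """Per-population diversity table (one row per sample set)."""
    table = collapse_haplotypes(sets, site_policy=site_policy)
    rows = []
    for st in sets:
        d = diversity_summary(st, table=table, site_policy=site_policy)
        rows.append(
            {"set": d.set_id, "N": d.n, "S": d.S, "H": d.H,
             "Hd": round(d.Hd, 3), "U": d.U, "pi": round(d.pi, 4),
             "theta_S": round(d.theta_S, 3)}
        )
    return pd.DataFrame(rows).set_index("set")
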