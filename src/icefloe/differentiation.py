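"""Genetic differentiation: distances, AMOVA, Phi_ST/F_ST, permutation tests.

The molecular fixation index Phi_ST is the among-population fraction of the
AMOVA decomposition of squared inter-individual Jukes-Cantor distances;
frequency-based F_ST is the same decomposition with distance 1 between
distinct haplotypes and 0 otherwise. Significance comes from permuting
individuals among populations; multiple comparisons are handled with
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .seqio import AlignedSampleSet


# ---------------------------------------------------------------------------
# distances

def jukes_cantor(p):
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3) for p in [0, 0.75).

    Accepts scalars or arrays; p >= 0.75 is outside the model's domain.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0) or np.any(p_arr >= 0.75):
        raise ValueError("Jukes-Cantor distance requires 0 <= p < 0.75")
    d = -0.75 * np.log1p(-4.0 * p_arr / 3.0)
    return float(d) if np.isscalar(p) else d


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    metric: str  # "jc" | "raw-p" | "haplotype-identity"

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.ids):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix must have zero diagonal")


def _pairwise_p(sets: list[AlignedSampleSet]) -> tuple[np.ndarray, list[str]]:
    """Pairwise proportion of differing sites with pairwise deletion."""
    enc = np.vstack([st.encoded() for st in sets])
    ids = [f"{st.set_id}:{sid}" for st in sets for sid in st.ids]
    if not np.any(enc >= 4):
        # no gaps/Ns: plain Hamming proportions
        from scipy.spatial.distance import pdist, squareform

        p = squareform(pdist(enc, metric="hamming"))
        return p, ids
    valid = (enc < 4).astype(np.float64)
    vv = valid @ valid.T
    match = np.zeros_like(vv)
    for b in range(4):
        X = (enc == b).astype(np.float64)
        match += X @ X.T
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(vv > 0, (vv - match) / np.maximum(vv, 1), 0.0)
    np.fill_diagonal(p, 0.0)
    return p, ids


def distance_matrix(sets: list[AlignedSampleSet], metric: str = "jc") -> DistanceMatrix:
    """Inter-individual distance matrix across one or more sample sets.

    Missing sites ('-'/'N') are dropped pairwise; ``metric`` is ``"jc"``
    (Jukes-Cantor), ``"raw-p"`` (uncorrected proportion), or
    ``"haplotype-identity"`` (0/1 distinct-sequence indicator).
    """
    p, ids = _pairwise_p(sets)
    if metric == "raw-p":
        d = p
    elif metric == "jc":
        d = jukes_cantor(p)
    elif metric == "haplotype-identity":
        d = (p > 0).astype(float)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(ids=ids, matrix=d, metric=metric)


# ---------------------------------------------------------------------------
# AMOVA

@dataclass
class AmovaResult:
    df: dict[str, float]
    ssd: dict[str, float]
    sigma2: dict[str, float]
    pct: dict[str, float]
    phi_st: float
    phi_ct: float | None = None
    phi_sc: float | None = None


def _ssd(d2: np.ndarray, idx: np.ndarray) -> float:
    """SSD of a block: (1 / 2n) * sum over the full sub-matrix of d^2."""
    sub = d2[np.ix_(idx, idx)]
    return float(sub.sum() / (2 * len(idx)))


def amova(
    dist: DistanceMatrix | np.ndarray,
    labels: list[str] | np.ndarray,
    groups: dict[str, list[str]] | None = None,
) -> AmovaResult:
    """Hierarchical analysis of molecular variance.

    ``labels`` assigns each row of the distance matrix to a population.
    Without ``groups`` the decomposition is two-level (among / within
    populations, yielding Phi_ST); with ``groups`` (group -> population
    labels) it is three-level, yielding Phi_CT, Phi_SC and Phi_ST.
    Variance components follow the standard expected-mean-square
    coefficients for unbalanced designs. Ratios with a zero denominator are
    reported as 0 (monomorphic data).
    """
    d = dist.matrix if isinstance(dist, DistanceMatrix) else np.asarray(dist)
    labels = np.asarray(labels)
    N = d.shape[0]
    if labels.shape[0] != N:
        raise ValueError("labels must align with the distance matrix")
    pops = list(dict.fromkeys(labels.tolist()))
    if len(pops) < 2:
        raise ValueError("AMOVA requires at least 2 populations")
    pop_idx = {p: np.flatnonzero(labels == p) for p in pops}
    sizes = {p: len(ix) for p, ix in pop_idx.items()}
    for p, np_ in sizes.items():
        if np_ < 2:
            raise ValueError(
                f"population {p!r} has n={np_}; merge singleton populations"
            )
    d2 = d**2
    ssd_total = _ssd(d2, np.arange(N))
    ssd_wp = sum(_ssd(d2, pop_idx[p]) for p in pops)

    if groups is None:
        P = len(pops)
        df_ap, df_wp = P - 1, N - P
        ssd_ap = ssd_total - ssd_wp
        ms_wp = ssd_wp / df_wp
        ms_ap = ssd_ap / df_ap
        n_prime = (N - sum(n**2 for n in sizes.values()) / N) / (P - 1)
        sigma_w = ms_wp
        sigma_a = (ms_ap - ms_wp) / n_prime
        total = sigma_a + sigma_w
        phi = sigma_a / total if total > 0 else 0.0
        pct_den = total if total > 0 else 1.0
        return AmovaResult(
            df={"among_populations": df_ap, "within_populations": df_wp},
            ssd={"among_populations": ssd_ap, "within_populations": ssd_wp,
                 "total": ssd_total},
            sigma2={"among_populations": sigma_a, "within_populations": sigma_w},
            pct={"among_populations": 100 * sigma_a / pct_den,
                 "within_populations": 100 * sigma_w / pct_den},
            phi_st=float(phi),
        )

    # three-level design
    group_names = list(groups)
    pop_to_group = {}
    for gname, plist in groups.items():
        for p in plist:
            pop_to_group[p] = gname
    missing = [p for p in pops if p not in pop_to_group]
    if missing:
        raise ValueError(f"populations not assigned to a group: {missing}")
    G = len(group_names)
    P = len(pops)
    group_idx = {
        g: np.concatenate([pop_idx[p] for p in groups[g] if p in pop_idx])
        for g in group_names
    }
    Ng = {g: len(ix) for g, ix in group_idx.items()}
    ssd_wg = sum(_ssd(d2, group_idx[g]) for g in group_names)
    ssd_ag = ssd_total - ssd_wg
    ssd_ap_wg = ssd_wg - ssd_wp
    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    ms_wp = ssd_wp / df_wp
    ms_ap = ssd_ap_wg / df_ap
    ms_ag = ssd_ag / df_ag
    sum_n2_over_Ng = sum(
        sum(sizes[p]**2 for p in groups[g] if p in sizes) / Ng[g]
        for g in group_names
    )
    n1 = (N - sum_n2_over_Ng) / (P - G)
    n2 = (sum_n2_over_Ng - sum(sizes[p]**2 for p in pops) / N) / (G - 1)
    n3 = (N - sum(Ng[g]**2 for g in group_names) / N) / (G - 1)
    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n1
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
    total = sigma_a + sigma_b + sigma_c
    pct_den = total if total > 0 else 1.0
    phi_st = (sigma_a + sigma_b) / total if total > 0 else 0.0
    phi_ct = sigma_a / total if total > 0 else 0.0
    denom_sc = sigma_b + sigma_c
    phi_sc = sigma_b / denom_sc if denom_sc > 0 else 0.0
    return AmovaResult(
        df={"among_groups": df_ag, "among_populations": df_ap,
            "within_populations": df_wp},
        ssd={"among_groups": ssd_ag, "among_populations": ssd_ap_wg,
             "within_populations": ssd_wp, "total": ssd_total},
        sigma2={"among_groups": sigma_a, "among_populations": sigma_b,
                "within_populations": sigma_c},
        pct={"among_groups": 100 * sigma_a / pct_den,
             "among_populations": 100 * sigma_b / pct_den,
             "within_populations": 100 * sigma_c / pct_den},
        phi_st=float(phi_st),
        phi_ct=float(phi_ct),
        phi_sc=float(phi_sc),
    )


def _phi_from_d2(d2: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> float:
    """Two-population Phi_ST straight from a squared-distance matrix."""
    N = len(idx_a) + len(idx_b)
    all_idx = np.concatenate([idx_a, idx_b])
    ssd_total = _ssd(d2, all_idx)
    ssd_wp = _ssd(d2, idx_a) + _ssd(d2, idx_b)
    df_wp = N - 2
    ms_wp = ssd_wp / df_wp
    ms_ap = ssd_total - ssd_wp  # df = 1
    n_prime = (N - (len(idx_a)**2 + len(idx_b)**2) / N)
    sigma_w = ms_wp
    sigma_a = (ms_ap - ms_wp) / n_prime
    total = sigma_a + sigma_w
    return float(sigma_a / total) if total > 0 else 0.0


def pairwise_phi_st(
    set_a: AlignedSampleSet, set_b: AlignedSampleSet, metric: str = "jc"
) -> float:
    """Pairwise Phi_ST between two sample sets (two-level AMOVA ratio)."""
    dm = distance_matrix([set_a, set_b], metric=metric)
    d2 = dm.matrix**2
    idx_a = np.arange(set_a.n)
    idx_b = np.arange(set_a.n, set_a.n + set_b.n)
    return _phi_from_d2(d2, idx_a, idx_b)


def frequency_f_st(set_a: AlignedSampleSet, set_b: AlignedSampleSet) -> float:
    """Frequency-based F_ST: the same AMOVA with 0/1 haplotype distances."""
    return pairwise_phi_st(set_a, set_b, metric="haplotype-identity")


# ---------------------------------------------------------------------------
# permutation test

def permutation_test(
    set_a: AlignedSampleSet,
    set_b: AlignedSampleSet,
    n_perm: int = 10_000,
    seed: int | None = None,
    metric: str = "jc",
) -> tuple[float, float]:
    """Permutation p-value for pairwise Phi_ST.

    Individuals are permuted among the two populations with sizes held
    fixed (Arlequin convention). Returns ``(observed_phi, p_value)`` with
    the +1-corrected estimator p = (1 + #{perm >= obs}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    dm = distance_matrix([set_a, set_b], metric=metric)
    d2 = dm.matrix**2
    na, nb = set_a.n, set_b.n
    N = na + nb
    idx_a = np.arange(na)
    idx_b = np.arange(na, N)
    observed = _phi_from_d2(d2, idx_a, idx_b)
    rng = np.random.default_rng(seed)
    perm_stats = permuted_phi_stats(d2, na, nb, n_perm, rng)
    count = int(np.sum(perm_stats >= observed))
    p = (1 + count) / (n_perm + 1)
    return observed, float(p)


def permuted_phi_stats(
    d2: np.ndarray, na: int, nb: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized permutation distribution of two-population Phi_ST."""
    N = na + nb
    total_sum = d2.sum()
    df_wp = N - 2
    n_prime = N - (na**2 + nb**2) / N
    perms = np.empty((n_perm, N), dtype=np.intp)
    for r in range(n_perm):
        perms[r] = rng.permutation(N)
    masks_a = np.zeros((n_perm, N))
    rows = np.repeat(np.arange(n_perm), na)
    masks_a[rows, perms[:, :na].ravel()] = 1.0
    # within-group full-matrix sums per permutation via quadratic forms
    qa = np.einsum("pi,ij,pj->p", masks_a, d2, masks_a)
    masks_b = 1.0 - masks_a
    qb = np.einsum("pi,ij,pj->p", masks_b, d2, masks_b)
    ssd_total = total_sum / (2 * N)
    ssd_wp = qa / (2 * na) + qb / (2 * nb)
    ms_wp = ssd_wp / df_wp
    ms_ap = ssd_total - ssd_wp
    sigma_a = (ms_ap - ms_wp) / n_prime
    total = sigma_a + ms_wp
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(total > 0, sigma_a / np.where(total == 0, 1, total), 0.0)
    return phi


def fdr_correct(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at level q."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values given")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


# ---------------------------------------------------------------------------
# pairwise comparison table

@dataclass
class PairwiseComparisonResult:
    set_a: str
    set_b: str
    phi_st: float
    f_st: float
    p_value: float
    n_permutations: int
    fdr_significant: bool = field(default=False)


def pairwise_comparisons(
    sets: list[AlignedSampleSet],
    n_perm: int = 10_000,
    seed: int | None = None,
    q: float = 0.05,
) -> list[PairwiseComparisonResult]:
    """All pairwise Phi_ST/F_ST with permutation p-values and FDR flags."""
    rng = np.random.default_rng(seed)
    results: list[PairwiseComparisonResult] = []
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            sub_seed = int(rng.integers(2**31 - 1))
            phi, p = permutation_test(sets[i], sets[j], n_perm=n_perm, seed=sub_seed)
            fst = frequency_f_st(sets[i], sets[j])
            results.append(
                PairwiseComparisonResult(
                    set_a=sets[i].set_id, set_b=sets[j].set_id,
                    phi_st=phi, f_st=fst, p_value=p, n_permutations=n_perm,
                )
            )
    flags = fdr_correct([r.p_value for r in results], q=q)
    for r, f in zip(results, flags):
        r.fdr_significant = bool(f)
    return results


def comparison_matrix(
    results: list[PairwiseComparisonResult], set_ids: list[str]
) -> pd.DataFrame:
    """Square table: Phi_ST below the diagonal, frequency F_ST above."""
    m = pd.DataFrame(np.nan, index=set_ids, columns=set_ids)
    for r in results:
        m.loc[r.set_b, r.set_a] = round(r.phi_st, 3)  # lower triangle
        m.loc[r.set_a, r.set_b] = round(r.f_st, 3)    # upper triangle
    np.fill_diagonal(m.values, 0.0)
    return m
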