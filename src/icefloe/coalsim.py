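"""Serial (heterochronous) coalescent simulator with HKY+Gamma mutation.

Backward-in-time haploid coalescent over multiple demes: within a deme of
female effective size N each lineage pair coalesces at rate 1/N per
generation; lineages relocate between demes at the backward migration
rates m[i][j]; tips sampled at different ages enter the genealogy at those
ages; historical events (size changes, lineage movements/divergences,
migration-matrix updates) apply at fixed times. Sequences are evolved on
the genealogy under HKY with continuous Gamma rate variation across sites.

Times are in generations before present throughout. The matrilineal
(mtDNA) interpretation is a haploid coalescent on female effective sizes.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .seqio import AlignedSampleSet

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# scenario description

@dataclass
class MutationModel:
    """HKY+Gamma mutation model.

    ``rate_per_site_per_my`` is either a fixed rate or a ``(lo, hi)`` tuple
    for a uniform prior, in substitutions per site per million years per
    lineage (so "2% per my" is 0.02). ``gamma_shape`` is the alpha of the
    continuous among-site rate distribution (mean 1); ``None`` disables
    rate variation.
    """

    kappa: float = 10.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: float | None = 0.5
    rate_per_site_per_my: float | tuple[float, float] = (0.02, 0.063)

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.base_freqs), 1.0, abs_tol=1e-9):
            raise ValueError("base frequencies must sum to 1")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        r = self.rate_per_site_per_my
        if isinstance(r, tuple):
            lo, hi = r
            if not 0 < lo <= hi:
                raise ValueError("rate prior bounds must satisfy 0 < lo <= hi")
        elif r < 0:
            raise ValueError("mutation rate must be non-negative")

    def draw_rate(self, rng: np.random.Generator) -> float:
        r = self.rate_per_site_per_my
        if isinstance(r, tuple):
            return float(rng.uniform(r[0], r[1]))
        return float(r)


def rate_per_generation(rate_per_site_per_my: float, generation_time_years: float) -> float:
    """Convert substitutions/site/my (per lineage) to per site per generation."""
    return rate_per_site_per_my * generation_time_years / 1e6


@dataclass
class SamplingEvent:
    """n samples taken from ``deme`` at ``age_generations``, labelled ``label``."""

    deme: str
    n: int
    age_generations: float = 0.0
    label: str | None = None
    age_years: float | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("sampling event needs n >= 1")
        if self.age_generations < 0:
            raise ValueError("sampling age must be non-negative")
        if self.label is None:
            self.label = self.deme


@dataclass
class HistoricalEvent:
    """A demographic event at ``time`` generations before present.

    kinds:
      - ``size_change``: deme -> new_size (absolute) or multiplier applied
        to the deme's current size; either may be ``("uniform", lo, hi)``
        to be drawn per replicate.
      - ``move_lineages``: each lineage in ``source`` moves to ``sink``
        with probability ``proportion`` (1.0 = deme merge / divergence).
      - ``migration_update``: replace the backward migration matrix.
    """

    time: float
    kind: str
    deme: str | None = None
    new_size: float | tuple | None = None
    multiplier: float | tuple | None = None
    source: str | None = None
    sink: str | None = None
    proportion: float = 1.0
    matrix: dict[str, dict[str, float]] | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("event time must be non-negative")
        if self.kind not in ("size_change", "move_lineages", "migration_update"):
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class DemographicScenario:
    """Demes, sampling design, history, migration, and mutation model."""

    demes: dict[str, float]  # deme id -> female effective size (individuals)
    sampling_events: list[SamplingEvent]
    historical_events: list[HistoricalEvent] = field(default_factory=list)
    migration: dict[str, dict[str, float]] = field(default_factory=dict)
    generation_time_years: float = 52.0
    mutation: MutationModel = field(default_factory=MutationModel)
    sequence_length: int = 370
    label: str = "scenario"
    time_cap: float = 5e7

    def __post_init__(self) -> None:
        for d, N in self.demes.items():
            if isinstance(N, tuple):
                if not (N[0] == "uniform" and 0 < N[1] <= N[2]):
                    raise ValueError(f"deme {d!r} has invalid size prior {N!r}")
            elif N <= 0:
                raise ValueError(f"deme {d!r} has non-positive size")
        for ev in self.sampling_events:
            if ev.deme not in self.demes:
                raise ValueError(f"sampling event references unknown deme {ev.deme!r}")
        times = [e.time for e in self.historical_events]
        if times != sorted(times):
            raise ValueError("historical events must be ordered by time")
        for row_id, row in self.migration.items():
            if row_id not in self.demes:
                raise ValueError(f"migration row for unknown deme {row_id!r}")
            s = sum(row.values())
            if any(v < 0 for v in row.values()) or s > 1 + 1e-9:
                raise ValueError("migration rates must be >= 0 with row sum <= 1")

    def total_samples(self) -> int:
        return sum(ev.n for ev in self.sampling_events)


def census_to_female_ne(census_N: float) -> int:
    """Female effective size from census size: N/6.

    Assumes a 1:1 male:female ratio, a 1.5:1 ratio of all individuals to
    adults, and Ne/N = 0.5, i.e. N_f = N * (1/1.5) * 0.5 * 0.5 = N/6,
    rounded to the nearest whole female.
    """
    if census_N <= 0:
        raise ValueError("census size must be positive")
    nf = round(census_N / 6.0)
    if nf < 1:
        raise ValueError(
            f"census size {census_N} maps to a female Ne below 1; "
            "population too small to represent"
        )
    return int(nf)


# ---------------------------------------------------------------------------
# genealogy

@dataclass
class GeneGenealogy:
    """Binary genealogy over sampled lineages.

    Node arrays of length 2n-1: tips are nodes 0..n-1 in sampling order;
    ``parent`` is -1 for the root; ``time`` is in generations before
    present (tips sit at their sampling ages).
    """

    parent: np.ndarray
    time: np.ndarray
    tip_labels: list[str]
    tip_ids: list[str]
    tip_ages: np.ndarray
    node_deme: list[str]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def tmrca(self) -> float:
        return float(self.time[self.root])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node (0 at the root)."""
        bl = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        bl[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return bl

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def preorder(self) -> list[int]:
        children: dict[int, list[int]] = {}
        for node, par in enumerate(self.parent):
            if par >= 0:
                children.setdefault(int(par), []).append(node)
        order = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(children.get(node, ()))
        return order

    def to_newick(self) -> str:
        children: dict[int, list[int]] = {}
        for node, par in enumerate(self.parent):
            if par >= 0:
                children.setdefault(int(par), []).append(node)

        def fmt(node: int) -> str:
            par = self.parent[node]
            bl = self.time[par] - self.time[node] if par >= 0 else 0.0
            if node < self.n_tips:
                return f"{self.tip_ids[node]}:{bl:.6g}"
            inner = ",".join(fmt(c) for c in children[node])
            return f"({inner}):{bl:.6g}"

        return fmt(self.root) + ";"


class SimulationError(RuntimeError):
    pass


def _draw_sizes(scenario: DemographicScenario, rng: np.random.Generator):
    """Resolve any per-replicate ('uniform', lo, hi) sizes/multipliers."""

    def resolve(v):
        if isinstance(v, tuple) and len(v) == 3 and v[0] == "uniform":
            return float(rng.uniform(v[1], v[2]))
        return v

    demes = {d: resolve(N) for d, N in scenario.demes.items()}
    events = []
    for ev in scenario.historical_events:
        events.append(
            replace(ev, new_size=resolve(ev.new_size), multiplier=resolve(ev.multiplier))
        )
    return demes, events


def simulate_genealogy(
    scenario: DemographicScenario, rng: np.random.Generator
) -> GeneGenealogy:
    """Simulate one gene genealogy under the scenario.

    Continuous-time approximation: coalescence within deme i at rate
    k_i(k_i-1)/(2 N_i) per generation, backward migration i->j at rate
    m[i][j] per lineage per generation, with exact event times between
    breakpoints (tip activations and historical events).
    """
    n = scenario.total_samples()
    if n < 2:
        raise ValueError("need at least 2 samples in total")
    sizes, events = _draw_sizes(scenario, rng)
    migration = {d: dict(scenario.migration.get(d, {})) for d in sizes}

    # tips in sampling-event order
    tip_labels: list[str] = []
    tip_ids: list[str] = []
    tip_ages: list[float] = []
    tip_deme: list[str] = []
    label_counter: dict[str, int] = {}
    for ev in scenario.sampling_events:
        for _ in range(ev.n):
            k = label_counter.get(ev.label, 0)
            label_counter[ev.label] = k + 1
            tip_labels.append(ev.label)
            tip_ids.append(f"{ev.label}_{k}")
            tip_ages.append(ev.age_generations)
            tip_deme.append(ev.deme)

    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes)
    node_time[:n] = tip_ages
    node_deme: list[str] = list(tip_deme) + [""] * (n - 1)

    # breakpoints: tip activations and historical events, merged by time
    pending_tips = sorted(range(n), key=lambda i: tip_ages[i])
    breakpoints: list[tuple[float, str, object]] = [
        (tip_ages[i], "tip", i) for i in pending_tips
    ] + [(ev.time, "event", ev) for ev in events]
    breakpoints.sort(key=lambda x: (x[0], 0 if x[1] == "tip" else 1))

    active: dict[str, list[int]] = {d: [] for d in sizes}
    py_rng = random.Random(int(rng.integers(2**63)))
    t = 0.0
    next_node = n
    bp = 0
    remaining_tips = n

    def n_active() -> int:
        return sum(len(v) for v in active.values())

    while True:
        if n_active() <= 1 and remaining_tips == 0:
            break
        # total rates under current state
        coal_rate = 0.0
        mig_rate = 0.0
        for d, lin in active.items():
            k = len(lin)
            if k >= 2:
                if sizes[d] <= 0:
                    raise SimulationError(f"zero-size deme {d!r} holds lineages")
                coal_rate += k * (k - 1) / (2.0 * sizes[d])
            if k:
                mig_rate += k * sum(migration.get(d, {}).values())
        total_rate = coal_rate + mig_rate
        next_bp = breakpoints[bp][0] if bp < len(breakpoints) else math.inf
        if total_rate <= 0:
            if math.isinf(next_bp):
                raise SimulationError(
                    "no common ancestor reachable (disconnected demes?)"
                )
            t = next_bp
        else:
            dt = py_rng.expovariate(total_rate)
            if t + dt >= next_bp:
                t = next_bp
            else:
                t += dt
                if t > scenario.time_cap:
                    raise SimulationError(
                        f"simulation exceeded time cap {scenario.time_cap:g} "
                        "generations; demes may be effectively disconnected"
                    )
                u = py_rng.random() * total_rate
                if u < coal_rate:
                    # choose deme by coalescence weight
                    acc = 0.0
                    for d, lin in active.items():
                        k = len(lin)
                        if k >= 2:
                            acc += k * (k - 1) / (2.0 * sizes[d])
                            if u < acc:
                                i = py_rng.randrange(k)
                                j = py_rng.randrange(k - 1)
                                if j >= i:
                                    j += 1
                                a, b = lin[i], lin[j]
                                for x in sorted((i, j), reverse=True):
                                    lin.pop(x)
                                parent[a] = next_node
                                parent[b] = next_node
                                node_time[next_node] = t
                                node_deme[next_node] = d
                                lin.append(next_node)
                                next_node += 1
                                break
                else:
                    u -= coal_rate
                    acc = 0.0
                    done = False
                    for d, lin in active.items():
                        if done:
                            break
                        k = len(lin)
                        if not k:
                            continue
                        for dest, m in migration.get(d, {}).items():
                            acc += k * m
                            if u < acc:
                                i = py_rng.randrange(k)
                                node = lin.pop(i)
                                active[dest].append(node)
                                done = True
                                break
                continue
        # at a breakpoint
        if bp >= len(breakpoints):
            # total_rate was 0 with no breakpoints left
            raise SimulationError("stalled with no events and no rates")
        while bp < len(breakpoints) and breakpoints[bp][0] <= t:
            _, kind, payload = breakpoints[bp]
            bp += 1
            if kind == "tip":
                i = payload
                active[tip_deme[i]].append(i)
                remaining_tips -= 1
            else:
                ev = payload
                if ev.kind == "size_change":
                    if ev.new_size is not None:
                        sizes[ev.deme] = float(ev.new_size)
                    elif ev.multiplier is not None:
                        sizes[ev.deme] *= float(ev.multiplier)
                    if sizes[ev.deme] <= 0:
                        raise SimulationError(
                            f"size change leaves deme {ev.deme!r} non-positive"
                        )
                elif ev.kind == "move_lineages":
                    src = active[ev.source]
                    moving = [x for x in src if py_rng.random() < ev.proportion]
                    active[ev.source] = [x for x in src if x not in moving]
                    active[ev.sink].extend(moving)
                elif ev.kind == "migration_update":
                    migration = {d: dict(ev.matrix.get(d, {})) for d in sizes}

    return GeneGenealogy(
        parent=parent,
        time=node_time,
        tip_labels=tip_labels,
        tip_ids=tip_ids,
        tip_ages=np.asarray(tip_ages, dtype=float),
        node_deme=node_deme,
    )


# ---------------------------------------------------------------------------
# HKY+Gamma mutation

def hky_rate_matrix(kappa: float, base_freqs: Sequence[float]) -> np.ndarray:
    """HKY85 generator, scaled to one expected substitution per unit time."""
    pi = np.asarray(base_freqs, dtype=float)
    Q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            Q[i, j] = kappa * pi[j] if (i, j) in transitions else pi[j]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -float(np.dot(pi, np.diag(Q)))
    return Q / mean_rate


class _HKYPropagator:
    """Uniformized HKY jump sampler for exact CTMC endpoint states.

    With dominating rate q_max = max_i(-Q_ii), candidate events occur as a
    Poisson process at rate q_max and each candidate applies the jump
    matrix J = I + Q/q_max (self-jumps allowed). This reproduces the exact
    transition law P(t) = exp(Qt) while letting sites without candidates be
    copied wholesale from the parent.
    """

    def __init__(self, kappa: float, base_freqs: Sequence[float]):
        Q = hky_rate_matrix(kappa, base_freqs)
        self.q_max = float(np.max(-np.diag(Q)))
        J = np.eye(4) + Q / self.q_max
        self.jump_cum = np.cumsum(J, axis=1)

    def evolve_branch(
        self,
        parent_states: np.ndarray,
        mu_bl: float,
        site_rates: np.ndarray,
        rate_cum: np.ndarray,
        rate_total: float,
        rng: np.random.Generator,
    ) -> np.ndarray:
        """Child states for one branch of expected distance mu_bl per site."""
        child = parent_states.copy()
        lam = self.q_max * mu_bl * rate_total
        k = rng.poisson(lam)
        if k == 0:
            return child
        # candidate sites ~ site_rates (with replacement: multiple jumps ok)
        sites = np.searchsorted(rate_cum, rng.random(k) * rate_total)
        for s in sites:
            u = rng.random()
            child[s] = np.searchsorted(self.jump_cum[child[s]], u)
        return child


def apply_mutations(
    genealogy: GeneGenealogy,
    model: MutationModel,
    length: int,
    mu_per_generation: float,
    rng: np.random.Generator,
) -> dict[str, AlignedSampleSet]:
    """Evolve sequences down the genealogy under HKY+Gamma.

    Per-site rate multipliers are Gamma(alpha, mean 1); the root sequence
    is drawn from the stationary base frequencies; along each branch the
    child states are sampled exactly from the HKY transition law via
    uniformization (Poisson candidate events at the dominating rate).
    Returns one AlignedSampleSet per sampling-event label.
    """
    if length <= 0:
        raise ValueError("sequence length must be positive")
    if mu_per_generation < 0:
        raise ValueError("mutation rate must be non-negative")
    if model.gamma_shape is not None:
        site_rates = rng.gamma(model.gamma_shape, 1.0 / model.gamma_shape, size=length)
    else:
        site_rates = np.ones(length)
    rate_cum = np.cumsum(site_rates)
    rate_total = float(rate_cum[-1])
    pi = np.asarray(model.base_freqs)
    states = np.empty((genealogy.n_nodes, length), dtype=np.int8)
    root = genealogy.root
    states[root] = rng.choice(4, size=length, p=pi)
    if mu_per_generation > 0:
        prop = _HKYPropagator(model.kappa, model.base_freqs)
        bl = genealogy.branch_lengths()
        for node in genealogy.preorder():
            if node == root:
                continue
            states[node] = prop.evolve_branch(
                states[genealogy.parent[node]],
                mu_per_generation * bl[node],
                site_rates, rate_cum, rate_total, rng,
            )
    else:
        for node in genealogy.preorder():
            if node != root:
                states[node] = states[genealogy.parent[node]]

    out: dict[str, AlignedSampleSet] = {}
    labels = list(dict.fromkeys(genealogy.tip_labels))
    base_lut = np.frombuffer(_BASES.encode(), dtype=np.uint8)
    for lab in labels:
        idx = [i for i, l in enumerate(genealogy.tip_labels) if l == lab]
        block = states[idx]
        seqs = [base_lut[row].tobytes().decode() for row in block]
        st = AlignedSampleSet(
            set_id=lab,
            ids=[genealogy.tip_ids[i] for i in idx],
            seqs=seqs,
            ages=genealogy.tip_ages[idx],  # kept in generations
        )
        st._encoded_cache = block.astype(np.int8)
        out[lab] = st
    return out


def simulate_dataset(
    scenario: DemographicScenario, rng: np.random.Generator
) -> dict[str, AlignedSampleSet]:
    """One replicate: draw priors, simulate genealogy, mutate sequences.

    Returns one AlignedSampleSet per sampling-event label (ages carried in
    generations).
    """
    rate_my = scenario.mutation.draw_rate(rng)
    mu_g = rate_per_generation(rate_my, scenario.generation_time_years)
    genealogy = simulate_genealogy(scenario, rng)
    return apply_mutations(
        genealogy, scenario.mutation, scenario.sequence_length, mu_g, rng
    )


def replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Deterministic per-replicate substream: one seeded generator per run."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(replicate,)))
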