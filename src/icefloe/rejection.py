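"""Scenario rejection by comparing observed Phi_ST to simulated HPD intervals.

For each demographic scenario, many replicate datasets are simulated with
the empirical sampling design, pairwise Phi_ST is computed for each focal
comparison with the identical code path used for the observed data, and
the scenario is rejected when any observed value falls outside the 95%
highest-posterior-density interval of its simulated distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coalsim import DemographicScenario, SimulationError, replicate_rng, simulate_dataset
from .differentiation import pairwise_phi_st
from .seqio import AlignedSampleSet

#: the five focal comparisons; "CG" pools HBFB and BBDS
FOCAL_COMPARISONS = (
    ("BCB", "BBDS"),
    ("BCB", "CG"),
    ("BCB", "PRI"),
    ("PRI", "BBDS"),
    ("PRI", "CG"),
)


def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass*n)`` sorted points.

    Ties in window width are broken toward the lower start index. This is
    the sorted-window HPD for an empirical Monte-Carlo sample (no density
    smoothing).
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 20:
        raise ValueError("need at least 20 samples for an HPD interval")
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    k = int(np.ceil(mass * n))
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))  # argmin takes the first minimum: lower start
    return float(x[i]), float(x[i + k - 1])


def pool_sets(a: AlignedSampleSet, b: AlignedSampleSet, set_id: str) -> AlignedSampleSet:
    """Concatenate two sample sets under a new label (e.g. Canada-Greenland)."""
    return AlignedSampleSet(
        set_id=set_id,
        ids=[f"{a.set_id}:{i}" for i in a.ids] + [f"{b.set_id}:{i}" for i in b.ids],
        seqs=list(a.seqs) + list(b.seqs),
        ages=np.concatenate([a.ages, b.ages]),
    )


def _resolve(sets: dict[str, AlignedSampleSet], label: str) -> AlignedSampleSet:
    if label in sets:
        return sets[label]
    if label == "CG" and "HBFB" in sets and "BBDS" in sets:
        return pool_sets(sets["HBFB"], sets["BBDS"], "CG")
    raise KeyError(f"no sample set for comparison label {label!r}")


def compute_comparisons(
    sets: dict[str, AlignedSampleSet],
    comparisons,
    metric: str = "jc",
) -> dict[tuple[str, str], float]:
    """Pairwise Phi_ST for each (label_a, label_b) comparison."""
    out: dict[tuple[str, str], float] = {}
    cache: dict[str, AlignedSampleSet] = {}
    for a, b in comparisons:
        if a not in cache:
            cache[a] = _resolve(sets, a)
        if b not in cache:
            cache[b] = _resolve(sets, b)
        out[(a, b)] = pairwise_phi_st(cache[a], cache[b], metric=metric)
    return out


@dataclass
class ScenarioVerdict:
    scenario: str
    comparisons: list[tuple[str, str]]
    simulated: dict[tuple[str, str], np.ndarray]
    hpd_95: dict[tuple[str, str], tuple[float, float]]
    observed: dict[tuple[str, str], float]
    rejecting: list[tuple[str, str]] = field(default_factory=list)

    @property
    def decision(self) -> str:
        return "rejected" if self.rejecting else "retained"

    def summary_rows(self) -> list[dict]:
        rows = []
        for c in self.comparisons:
            lo, hi = self.hpd_95[c]
            rows.append({
                "scenario": self.scenario, "comparison": f"{c[0]}-{c[1]}",
                "observed": self.observed[c],
                "hpd_lo": lo, "hpd_hi": hi,
                "median": float(np.median(self.simulated[c])),
                "outside": c in self.rejecting,
            })
        return rows


def run_rejection(
    scenario: DemographicScenario,
    observed: dict[tuple[str, str], float],
    n_reps: int = 10_000,
    seed: int = 0,
    mass: float = 0.95,
    metric: str = "jc",
    max_failure_fraction: float = 0.05,
) -> ScenarioVerdict:
    """Simulate the scenario's Phi_ST distributions and apply the HPD rule.

    ``observed`` maps comparison tuples (subset of FOCAL_COMPARISONS or any
    labels resolvable from the scenario's sampling events) to observed
    Phi_ST. Each replicate simulates a full dataset with the scenario's
    sampling design and computes the same comparisons with the identical
    distance/statistic code path. The scenario is rejected when any
    observed value falls outside its 95% HPD interval.
    """
    if n_reps < 100:
        raise ValueError("use at least 100 replicates")
    labels = {ev.label for ev in scenario.sampling_events}
    if "HBFB" in labels and "BBDS" in labels:
        labels.add("CG")

    def resolvable(c):
        return c[0] in labels and c[1] in labels

    comparisons = [c for c in observed if resolvable(c)]
    if not comparisons:
        raise ValueError(
            f"scenario {scenario.label}: no observed comparison matches its "
            f"sampling labels {sorted(labels)}"
        )
    sims: dict[tuple[str, str], list[float]] = {c: [] for c in comparisons}
    failures = 0
    for r in range(n_reps):
        rng = replicate_rng(seed, r)
        try:
            sets = simulate_dataset(scenario, rng)
            vals = compute_comparisons(sets, comparisons, metric=metric)
        except SimulationError as exc:
            failures += 1
            if failures > max_failure_fraction * n_reps:
                raise SimulationError(
                    f"scenario {scenario.label}: {failures} simulation failures "
                    f"in {r + 1} replicates (last: {exc})"
                ) from exc
            continue
        for c, v in vals.items():
            sims[c].append(v)
    simulated = {c: np.asarray(v) for c, v in sims.items()}
    hpd = {c: hpd_interval(simulated[c], mass=mass) for c in comparisons}
    rejecting = [
        c for c in comparisons
        if not (hpd[c][0] <= observed[c] <= hpd[c][1])
    ]
    return ScenarioVerdict(
        scenario=scenario.label,
        comparisons=comparisons,
        simulated=simulated,
        hpd_95=hpd,
        observed=dict(observed),
        rejecting=rejecting,
    )


def duplicate_sensitivity(
    target: AlignedSampleSet,
    others: list[AlignedSampleSet],
    k_max: int = 5,
    candidate: str | None = None,
    metric: str = "jc",
):
    """Effect of serially removing repeated sequences on pairwise Phi_ST.

    Emulates the duplicated-individual robustness check: for k = 1..k_max,
    remove k copies of ``candidate`` (default: the target set's most common
    sequence) and recompute Phi_ST against every other set. Returns a list
    of rows with the per-k mean percentage change relative to the baseline.
    """
    if k_max >= target.n:
        raise ValueError("cannot remove as many sequences as the set holds")
    if candidate is None:
        seqs, counts = np.unique(target.seqs, return_counts=True)
        candidate = str(seqs[np.argmax(counts)])
    copies = [i for i, s in enumerate(target.seqs) if s == candidate]
    if not copies:
        raise ValueError("candidate sequence not present in the target set")
    if len(copies) < k_max:
        raise ValueError(
            f"candidate has only {len(copies)} copies; cannot remove {k_max}"
        )
    baseline = {o.set_id: pairwise_phi_st(target, o, metric=metric) for o in others}
    rows = []
    for k in range(1, k_max + 1):
        keep = [i for i in range(target.n) if i not in set(copies[:k])]
        reduced = target.subset(keep)
        deltas = []
        for o in others:
            phi = pairwise_phi_st(reduced, o, metric=metric)
            base = baseline[o.set_id]
            if base != 0:
                deltas.append(100.0 * (phi - base) / abs(base))
            else:
                deltas.append(0.0)
        rows.append({"k_removed": k, "mean_pct_change": float(np.mean(deltas)),
                     "per_set_pct": {o.set_id: d for o, d in zip(others, deltas)}})
    return rows
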