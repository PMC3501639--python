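"""The 36-scenario demographic design for the Canadian Arctic sample sets.

Three base timings of Atlantic-Pacific gene flow x four between-stock
structures x three migration rates. Structures:

  A: HBFB and BBDS as separate demes; the ancient PRI samples drawn from
     within BBDS.
  B: HBFB and BBDS combined into one Canada-Greenland deme; PRI drawn from
     within it.
  C: PRI as a separate (now-extirpated) population alongside HBFB, BBDS
     and BCB.
  D: PRI ancestral to BCB — the ancient samples are drawn from the BCB
     lineage itself.

Timings govern when the two ocean basins last exchanged migrants: under
timing 1 inter-basin gene flow stopped at the mid-Holocene ice maximum,
under timing 2 it persisted until the onset of the Little Ice Age, and
under timing 3 it is contemporary (continues to the present). Whaling is a
per-replicate bottleneck: each modern deme's present size is its
pre-whaling size times a residual fraction drawn from a uniform prior, and
the pre-whaling size is restored (backward in time) at the onset of
commercial whaling.

The structural parameters shipped here (sizes, event times) are explicit
reconstructions at census scale and are fully config-overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from itertools import product

import yaml

from .coalsim import (
    DemographicScenario,
    HistoricalEvent,
    MutationModel,
    SamplingEvent,
    census_to_female_ne,
)

TIMINGS = ("1", "2", "3")
STRUCTURES = ("A", "B", "C", "D")
MIGRATION_RATES = (0.1, 0.01, 0.001)

#: empirical sample sizes (Table-style N column) and the ancient-sample age
PRI_N, HBFB_N, BBDS_N, BCB_N = 38, 176, 89, 394
PRI_AGE_YEARS = 650.0  # midpoint of the 500-800 ybp occupation bracket


@dataclass
class ScenarioBankConfig:
    """Structural parameters of the scenario bank (reconstruction defaults).

    Census sizes are pre-whaling; female effective sizes are derived via
    ``census_to_female_ne`` (N/6). Times are years before present.
    """

    census_hbfb: float = 680.0
    census_bbds: float = 11_000.0
    census_bcb: float = 17_000.0
    census_pri: float = 1_000.0  # only used when PRI is its own deme (C)
    # uniform priors on post-whaling residual fractions
    hbfb_residual: tuple[float, float] = (0.01, 0.68)
    bbds_residual: tuple[float, float] = (0.01, 0.29)
    bcb_residual: tuple[float, float] = (0.10, 0.26)
    whaling_start_atlantic_y: float = 470.0  # commercial whaling from ~1540 AD
    whaling_start_pacific_y: float = 160.0   # BCB whaling from 1848
    # inter-basin gene-flow cutoffs (backward: migration off more recently
    # than the cutoff, on beyond it) for timings 1 and 2
    timing1_cutoff_y: float = 3_000.0  # mid-Holocene ice barrier
    timing2_cutoff_y: float = 550.0    # pre-Little-Ice-Age window
    ancestral_merge_y: float = 120_000.0  # single ancestral deme beyond this
    generation_time_years: float = 52.0
    sequence_length: int = 370
    mutation: MutationModel = field(default_factory=MutationModel)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["mutation"] = asdict(self.mutation)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioBankConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "mutation" in d:
            m = d["mutation"]
            for key in ("base_freqs",):
                if key in m and isinstance(m[key], list):
                    m[key] = tuple(m[key])
            if isinstance(m.get("rate_per_site_per_my"), list):
                m["rate_per_site_per_my"] = tuple(m["rate_per_site_per_my"])
            d["mutation"] = MutationModel(**m)
        for key in ("hbfb_residual", "bbds_residual", "bcb_residual"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def empirical_sampling_template(
    generation_time_years: float = 52.0,
    pool_canada_greenland: bool = False,
) -> list[SamplingEvent]:
    """Sampling design matching the empirical data sets.

    PRI: 38 ancient samples at ~650 ybp (12.5 generations at 52 y/gen);
    HBFB 176, BBDS 89, BCB 394 modern. With ``pool_canada_greenland`` the
    two modern Atlantic sets are replaced by one pooled event of 265.
    """
    pri_age_gen = PRI_AGE_YEARS / generation_time_years
    events = [SamplingEvent(deme="PRI", n=PRI_N, age_generations=pri_age_gen,
                            label="PRI", age_years=PRI_AGE_YEARS)]
    if pool_canada_greenland:
        events.append(SamplingEvent(deme="CG", n=HBFB_N + BBDS_N, label="CG"))
    else:
        events.append(SamplingEvent(deme="HBFB", n=HBFB_N, label="HBFB"))
        events.append(SamplingEvent(deme="BBDS", n=BBDS_N, label="BBDS"))
    events.append(SamplingEvent(deme="BCB", n=BCB_N, label="BCB"))
    return events


@dataclass
class ScenarioSpec:
    timing: str
    structure: str
    migration_rate: float

    @property
    def label(self) -> str:
        return f"{self.timing}{self.structure}_m{self.migration_rate:g}"


def _years_to_gen(y: float, gen_time: float) -> float:
    return y / gen_time


def build_scenario(
    spec: ScenarioSpec,
    config: ScenarioBankConfig | None = None,
    scale: float = 1.0,
) -> DemographicScenario:
    """Materialize one DemographicScenario from a (timing, structure, m) spec.

    ``scale`` multiplies sample sizes and effective sizes together, keeping
    theta = 2*N*mu and the migration rates (per-generation probabilities)
    unchanged; used for desk-scale runs.
    """
    cfg = config or ScenarioBankConfig()
    gt = cfg.generation_time_years
    m = spec.migration_rate

    def nf(census: float) -> float:
        return max(2.0, census_to_female_ne(census) * scale)

    # demes present at time 0 (modern), by structure
    if spec.structure == "A":
        demes = {"HBFB": nf(cfg.census_hbfb), "BBDS": nf(cfg.census_bbds),
                 "BCB": nf(cfg.census_bcb)}
        atlantic, pacific = ["HBFB", "BBDS"], ["BCB"]
        pri_deme = "BBDS"
    elif spec.structure == "B":
        demes = {"CG": nf(cfg.census_hbfb + cfg.census_bbds),
                 "BCB": nf(cfg.census_bcb)}
        atlantic, pacific = ["CG"], ["BCB"]
        pri_deme = "CG"
    elif spec.structure == "C":
        demes = {"HBFB": nf(cfg.census_hbfb), "BBDS": nf(cfg.census_bbds),
                 "PRI": nf(cfg.census_pri), "BCB": nf(cfg.census_bcb)}
        atlantic, pacific = ["HBFB", "BBDS", "PRI"], ["BCB"]
        pri_deme = "PRI"
    elif spec.structure == "D":
        demes = {"HBFB": nf(cfg.census_hbfb), "BBDS": nf(cfg.census_bbds),
                 "BCB": nf(cfg.census_bcb)}
        atlantic, pacific = ["HBFB", "BBDS"], ["BCB"]
        pri_deme = "BCB"
    else:
        raise ValueError(f"unknown structure {spec.structure!r}")

    def matrix(inter_basin: float) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for a in demes:
            row: dict[str, float] = {}
            for b in demes:
                if a == b:
                    continue
                same_basin = (a in atlantic) == (b in atlantic)
                row[b] = m if same_basin else inter_basin
            out[a] = row
        return out

    events: list[HistoricalEvent] = []
    # whaling bottlenecks: present size = residual * pre-whaling size;
    # size restored (backward) at the whaling onset
    residual_priors = {
        "HBFB": cfg.hbfb_residual, "BBDS": cfg.bbds_residual,
        "BCB": cfg.bcb_residual,
        "CG": cfg.bbds_residual,  # pooled deme follows the larger stock
    }
    whaling_times = {
        "HBFB": cfg.whaling_start_atlantic_y, "BBDS": cfg.whaling_start_atlantic_y,
        "CG": cfg.whaling_start_atlantic_y, "BCB": cfg.whaling_start_pacific_y,
    }
    deme_sizes: dict[str, object] = {}
    for d, pre_size in demes.items():
        if d in residual_priors:
            lo, hi = residual_priors[d]
            deme_sizes[d] = ("uniform", pre_size * lo, pre_size * hi)
            events.append(HistoricalEvent(
                time=_years_to_gen(whaling_times[d], gt),
                kind="size_change", deme=d, new_size=pre_size,
            ))
        else:
            deme_sizes[d] = pre_size  # PRI deme: no commercial-whaling event

    # inter-basin gene-flow timing
    if spec.timing in ("1", "2"):
        cutoff_y = cfg.timing1_cutoff_y if spec.timing == "1" else cfg.timing2_cutoff_y
        initial_migration = matrix(inter_basin=0.0)
        events.append(HistoricalEvent(
            time=_years_to_gen(cutoff_y, gt), kind="migration_update",
            matrix=matrix(inter_basin=m),
        ))
    else:
        initial_migration = matrix(inter_basin=m)

    # collapse everything into a single ancestral deme deep in the past
    anchor = "BCB"
    merge_t = _years_to_gen(cfg.ancestral_merge_y, gt)
    for d in demes:
        if d != anchor:
            events.append(HistoricalEvent(
                time=merge_t, kind="move_lineages", source=d, sink=anchor,
                proportion=1.0,
            ))

    events.sort(key=lambda e: e.time)
    sampling = empirical_sampling_template(gt, pool_canada_greenland=(spec.structure == "B"))
    if scale != 1.0:
        sampling = [SamplingEvent(deme=ev.deme, n=max(2, round(ev.n * scale)),
                                  age_generations=ev.age_generations,
                                  label=ev.label, age_years=ev.age_years)
                    for ev in sampling]
    # point PRI sampling at its host deme for this structure
    fixed = []
    for ev in sampling:
        deme = pri_deme if ev.label == "PRI" else ev.deme
        if deme not in demes:
            raise ValueError(
                f"scenario {spec.label}: sampling deme {deme!r} missing"
            )
        fixed.append(SamplingEvent(deme=deme, n=ev.n,
                                   age_generations=ev.age_generations,
                                   label=ev.label, age_years=ev.age_years))

    return DemographicScenario(
        demes=deme_sizes,  # type: ignore[arg-type]
        sampling_events=fixed,
        historical_events=events,
        migration=initial_migration,
        generation_time_years=gt,
        mutation=cfg.mutation,
        sequence_length=cfg.sequence_length,
        label=spec.label,
    )


def enumerate_scenarios(
    config: ScenarioBankConfig | None = None, scale: float = 1.0
) -> dict[str, DemographicScenario]:
    """The full 3 x 4 x 3 = 36 scenario bank, keyed by label."""
    bank: dict[str, DemographicScenario] = {}
    for timing, structure, m in product(TIMINGS, STRUCTURES, MIGRATION_RATES):
        spec = ScenarioSpec(timing=timing, structure=structure, migration_rate=m)
        bank[spec.label] = build_scenario(spec, config=config, scale=scale)
    return bank


def design_table() -> list[dict]:
    """The 36-row design as plain dicts (for listing/CLI)."""
    rows = []
    for timing, structure, m in product(TIMINGS, STRUCTURES, MIGRATION_RATES):
        spec = ScenarioSpec(timing, structure, m)
        rows.append({"label": spec.label, "timing": timing,
                     "structure": structure, "m": m})
    return rows
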