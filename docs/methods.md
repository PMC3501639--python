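# Methods

This note documents the models, conventions and numerical choices behind
`icefloe`, in the order the pipeline runs them. It states no empirical
result the test suite or `scripts/acceptance.py` does not itself compute.

## Sequence handling and site policy

Sample sets are equal-length aligned mtDNA D-loop sequences over
`{A,C,G,T,-,N}`, each sample carrying a sampling age in years before
present (0 for modern biopsies). The unstated but consequential convention
is how gapped/ambiguous columns enter each statistic:

- **Haplotype collapsing and segregating sites** use *complete deletion*:
  any column containing `-` or `N` anywhere in the pooled alignment is
  dropped, giving one fixed site mask. Reproducible S and H require a
  single mask; per-pair masks would make "number of haplotypes" depend on
  which pair you look at.
- **Inter-individual distances** use *pairwise deletion*: each pair is
  compared on the sites where both are called, and the Jukes-Cantor
  correction d = −¾ ln(1 − 4p/3) is applied to the resulting proportion.
  p ≥ 0.75 is outside the model's domain and raises rather than silently
  truncating.

IUPAC ambiguity codes other than N are rejected by default; an option
maps them to N. Both policies are explicit function arguments, so a user
can reproduce either convention.

## Diversity statistics

Standard estimators: Nei's unbiased haplotype diversity
Hd = n(1 − Σp²)/(n − 1); per-site nucleotide diversity π as the mean
uncorrected pairwise difference proportion over all n(n−1)/2 pairs;
Watterson's θ(S) = S / Σ_{i=1}^{n−1} 1/i on the per-locus scale (divide by
the retained length for per-site). Both θ scales are exposed because the
literature mixes them: per-locus values for a 370-bp D-loop fragment sit
in the 3–8 range while per-site π sits near 0.01. Published per-locus θ(S)
values for this kind of data do not always equal S/a_{n−1} exactly — the
effective site set and n conventions of older software differ — so the
package implements the textbook estimator and leaves reconciliation of
legacy tables to the user.

The 95% interval for Hd is a coalescent reconstruction: simulate the
standard neutral coalescent at the set's n and per-locus Watterson θ
(infinite-sites mutations dropped on branches at rate θ/2 per coalescent
time unit), compute Hd per replicate, and take the empirical 2.5/97.5
percentiles. This mirrors what interval-producing software in this field
does in spirit, but it is a reconstruction, not a re-implementation of any
particular program.

## AMOVA, Φ_ST and permutation tests

The decomposition follows the standard analysis of molecular variance:
with squared inter-individual distances d², SSD(total) = ΣΣd²/2N and each
block's SSD = ΣΣd²/2n over its own members; among-level sums of squares
follow by subtraction, variance components from the expected-mean-square
coefficients for unbalanced designs, and Φ statistics as component
ratios (two-level Φ_ST = σ²_a/(σ²_a + σ²_w); three-level Φ_CT, Φ_SC,
Φ_ST). Frequency-based F_ST is the identical machinery with 0/1
haplotype-identity distances — differentiation in frequencies only,
ignoring how different the haplotypes are. Negative estimates are
reported as computed (they are the unbiased estimator's way of saying
"zero, with noise"); a 0/0 ratio on monomorphic data is reported as 0.

The closed formulas are verified against a brute-force oracle (plain
double loops, written independently in the test suite) to 1e-10 on
hundreds of random unbalanced instances.

Significance: individuals are permuted among the two populations with
sizes preserved, and p = (1 + #{perm ≥ obs}) / (n_perm + 1); the +1
correction avoids p = 0 and makes the test valid at any n_perm. The
permutation null is computed vectorized (quadratic forms over permutation
masks) so 10⁴ permutations on hundreds of samples stay cheap. Multiple
comparisons use Benjamini-Hochberg step-up at q = 0.05 (q exposed;
delegated to statsmodels).

## Haplotype network

The "optimal minimum spanning network" is the union of all minimum
spanning trees of the complete Hamming-distance graph on haplotypes: an
edge (u,v,w) is in some MST exactly when u and v are not connected using
edges strictly shorter than w. This cut/cycle-property construction is
O(E log E) with union-find and is verified against exhaustive
spanning-tree enumeration for small node counts. One Kruskal MST is
marked "primary"; co-minimal extras carry an `alternative` flag.
Frequencies annotate nodes for rendering and never change topology.

## Serial coalescent simulator

Backward-in-time haploid coalescent, the natural model for matrilineal
mtDNA with female effective sizes:

- within a deme of size N, each lineage pair coalesces at rate 1/N per
  generation (continuous-time approximation with exponential waiting
  times — standard, and accurate for N ≫ n);
- backward migration: a lineage in deme i relocates to j at rate m[i][j]
  per generation (SIMCOAL convention: m is the probability a lineage's
  parent lived elsewhere);
- heterochronous tips activate at their sampling ages; historical events
  (size changes, lineage movements for divergence, migration-matrix
  updates) apply at fixed times between Gillespie steps;
- a configurable time cap (default 5×10⁷ generations) converts
  effectively disconnected demes into a clear error.

Units: times in generations; one generation = 52 years by default (the
bowhead value used throughout); mutation rates are entered as
substitutions/site/million years per lineage ("2% per my" = 0.02) and
converted as μ_gen = rate × generation_time / 10⁶, so 0.02/my at 52 y/gen
is 1.04×10⁻⁶. The conversion lives in one function so an alternative
convention (per pair of lineages) can be swapped in.

Calibration against analytic oracles is part of the acceptance suite:
E[TMRCA] = N for n = 2 (within 2% at 20,000 replicates), E[total branch
length] = 2N·Σ1/i, and the end-to-end estimator check E[π] = 2Nμ per site.
An independent cross-check compares the TMRCA distribution with msprime's
haploid simulator by a Kolmogorov-Smirnov test.

### Mutation model

HKY85 with unequal base frequencies and transition/transversion parameter
κ (default 10, typical of control-region data; the study's fitted value
is not published, so κ and the Γ shape are explicit parameters), plus
continuous Gamma(α, mean 1) rate multipliers per site (α default 0.5;
`None` disables heterogeneity). The generator matrix is normalized to one
expected substitution per unit distance.

Tip sequences are sampled exactly from the CTMC transition law by
*uniformization*: candidate events occur as a Poisson process at the
dominating rate q_max = max(−Q_ii), and each candidate applies the jump
matrix I + Q/q_max (self-jumps allowed). This is equal in distribution to
"mutations as a Poisson process along branches" but lets the typical
branch-site, which experiences no event, be copied wholesale — the
difference between milliseconds and tens of milliseconds per replicate.
Correctness is pinned by two tests: with κ=1 and equal frequencies the
observed divergence on long branches matches the Jukes-Cantor closed form
E[p] = ¾(1 − e^{−4d/3}), and simulated base composition matches the
stationary frequencies.

A note on finite sites: the analytic oracle E[π] = 2Nμ ignores multiple
hits. At θ = 0.01/site the finite-site depression of π is ≈1.3% with a
homogeneous clock but ≈5% under Γ(0.5) heterogeneity (fast sites
saturate). The calibration scenarios therefore run with heterogeneity
disabled — they calibrate the coalescent and mutation-count machinery,
not the saturation behavior, which is the mutation model's intended
biology rather than an error.

## Scenario bank

36 scenarios = 3 gene-flow timings × 4 structures × 3 migration rates
(0.1, 0.01, 0.001). Structures: (A) HBFB and BBDS separate with the
ancient PRI samples drawn from BBDS; (B) a pooled Canada-Greenland deme;
(C) PRI as its own, now-extirpated population; (D) PRI ancestral to BCB
(the ancient samples belong to the BCB lineage). Timings: inter-basin
migration zero more recently than a cutoff at 3,000 ybp (timing 1,
mid-Holocene ice barrier) or 550 ybp (timing 2, pre-Little-Ice-Age
window), or active to the present (timing 3, contemporary gene flow).

Whaling enters backward: each modern deme's present size is its
pre-whaling size times a residual fraction drawn per replicate from a
uniform prior — (0.01, 0.68) for HBFB, (0.01, 0.29) for BBDS, (0.10,
0.26) for BCB (configurable; the BCB residual is not pinned by a printed
number) — and a size-change event restores the pre-whaling size at the
onset of commercial whaling (≈470 ybp Atlantic, ≈160 ybp Pacific).
Female effective sizes derive from census sizes as N/6 (1:1 sex ratio,
1.5:1 total:adult, Ne/N = 0.5). The shipped pre-whaling census defaults
(HBFB 680, BBDS 11,000, BCB 17,000, PRI 1,000) and the event times are
explicit reconstructions at the literature's scale, not published fits;
every number is overridable through `ScenarioBankConfig` (YAML
round-trip provided). Scenario enumeration is a pure function of the
config: identical config, identical bank.

The sampling template matches the empirical design: PRI 38 at 650 ybp
(midpoint of the 500–800 ybp occupation bracket; 12.5 generations),
HBFB 176, BBDS 89, BCB 394 modern; Canada-Greenland pooling gives 265.

## Rejection framework

For each scenario, replicate datasets are simulated at the template
design, pairwise Φ_ST is computed for the five focal comparisons
(BCB–BBDS, BCB–CG, BCB–PRI, PRI–BBDS, PRI–CG; CG pools HBFB+BBDS) with
the *identical* distance/statistic code path used for observed data, and
the scenario is rejected when any observed value falls outside the 95%
highest-posterior-density interval of its simulated distribution.
Comparisons a scenario cannot express (BBDS alone under the pooled
structure B) are skipped for that scenario. Per-comparison flags are
reported alongside the overall any-rule decision.

The HPD of a Monte-Carlo sample is the sorted-window interval: the
shortest window over the sorted sample containing ⌈0.95 n⌉ points, ties
broken toward the lower start. No density smoothing — "HPD" is otherwise
underdetermined for raw samples — and the implementation is checked
against exhaustive window search.

**Desk-scale power.** A single non-recombining locus makes simulated
Φ_ST distributions intrinsically broad: at reduced sample scale even
m = 0.001 scenarios produce enough near-zero replicates that their 95%
HPDs reach below 0, so the demonstration sweep in the analysis driver and
acceptance script retains all 36 scenarios. That is the honest outcome at
that scale, not a property of the method: the dedicated recovery test
runs a strong-drift two-deme design (N = 40 per deme, 24 samples each,
5,000 sites, rate 6.3%/my) where the engine retains the generating
m = 0.1 scenario and rejects the m = 0.001 variant in ≥90% of 50 trials
at 500 replicates each. Discriminating the full bank the way the original
analysis did requires its full sample sizes, 10⁴ replicates per scenario,
and all five comparisons jointly.

Reproducibility: one seed per run; replicate r uses the deterministic
substream `SeedSequence(seed, spawn_key=(r,))`, so verdicts and intervals
are bit-stable under a fixed seed and independent across replicates.

## Duplicate screening

Probability of identity from sample allele frequencies (no
Hardy-Weinberg fitting): per locus PID_HW = Σp⁴ + Σ_{i<j}(2p_ip_j)² and
PID_sib = 0.25 + 0.5Σp² + 0.5(Σp²)² − 0.25Σp⁴, multiplied across loci;
PID_sib ≥ PID_HW always (property-tested). Genotype matching reports
exact pairs and near-pairs at ≤1–2 mismatching loci separately, ignoring
loci missing in either member of a pair.

The Φ_ST sensitivity analysis removes k = 1..5 copies of a repeated
sequence (by default the target set's most common haplotype) and reports
the mean percentage change against every other set. Percentage change is
relative to the baseline Φ_ST, so when the baseline is near zero —
as in weakly structured data — the percentages are large even though the
absolute movement is in the third decimal; read them together with the
baseline values.

## Synthetic study-shaped data

The generator emulates the empirical design so every stage runs without
downloads: six sample sets with sizes 38/176/89/394/24/38, 370-bp
alignments, PRI ancient at 650 ybp, Spitsbergen heterochronous with
per-sample ages uniform on 30–3,000 ybp, a shared dominant haplotype, and
population-private singletons. Internally it is one coalsim scenario:
four demes (Canada-Greenland, BCB, Okhotsk, Spitsbergen; PRI sampled from
the BCB lineage), symmetric migration 0.05/generation, sizes set so the
largest deme's 2Nμ is 0.012/site at a fixed 4%/my clock — chosen once to
land per-set haplotype diversity in the 0.6–0.9 band and π near 0.01
typical of bowhead control-region data. The dominant-haplotype pattern is
enforced by resampling up to a retry cap (~20% of draws satisfy it, so
the default 20 retries almost always succeed); on exhaustion the best
attempt is returned with a warning.

What the generator does **not** emulate: the real data's haplotype
richness (76 haplotypes in 759 sequences) exceeds neutral-equilibrium
expectations at this θ — real D-loops carry hypervariable sites and
historical structure the four-deme scenario does not encode; realized
diversity also varies a lot between seeds, because a single locus is one
draw from a high-variance genealogical process. Passing tests therefore
demonstrate correct machinery and study-shaped marginals, not a forgery
of the GenBank haplotype spectrum. Test fixtures divide sample sizes by 4
(effective sizes untouched, so θ is preserved) to keep the suite fast.

## Known limitations

- No recombination, selection, or diploid mode in the simulator (mtDNA
  scope); no median-joining network or statistical-parsimony connection
  limits; no exact tests of differentiation or microsatellite R_ST.
- The scenario bank's structural parameters are reconstructions; results
  from the shipped defaults characterize the machinery, not the published
  study system.
- AMOVA treats ancient sample sets as ordinary populations (no explicit
  time stratification) — the convention the original spatial analysis
  used.
- Continuous-time migration/coalescence approximates discrete
  generations; at m = 0.1 per generation the rate interpretation differs
  from the per-generation probability by O(m²).
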