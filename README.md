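# icefloe

Population-genetic analysis of Holarctic bowhead whale (*Balaena
mysticetus*) mitochondrial D-loop sequences: diversity statistics,
AMOVA-based differentiation, haplotype networks, and a serial-coalescent
simulation framework that tests demographic and whaling hypotheses by
interval rejection.

## The scientific problem

Bowhead whales are managed as five putative stocks (Hudson Bay-Foxe Basin,
Baffin Bay-Davis Strait, Bering-Beaufort-Chukchi, Okhotsk, Spitsbergen).
Whether Arctic sea ice has actually been a barrier to maternal gene flow —
and how four centuries of commercial whaling reshaped genetic structure —
can be probed by comparing modern biopsy sequences with ancient DNA from
archaeological material (Prince Regent Inlet baleen/bone at 500–800 ybp,
Spitsbergen remains spanning 30–3,000 ybp). This package implements that
analysis as a tested, reusable pipeline for anyone combining heterochronous
mtDNA sample sets.

## What it computes

- **Diversity panel** per sample set: segregating sites *S*, haplotype
  count *H*, Nei's unbiased haplotype diversity
  *Hd = n(1 − Σp<sub>i</sub>²)/(n − 1)*, private haplotypes *U*, per-site
  nucleotide diversity π, and Watterson's
  *θ(S) = S / Σ<sub>i=1</sub><sup>n−1</sup> 1/i*, with a coalescent
  resampling 95% interval for *Hd*.
- **Differentiation**: pairwise Φ<sub>ST</sub> (two-level AMOVA ratio
  σ²<sub>a</sub>/(σ²<sub>a</sub>+σ²<sub>w</sub>) on squared Jukes-Cantor
  distances, *d = −¾ ln(1 − 4p/3)*), frequency-based F<sub>ST</sub> (same
  decomposition with 0/1 haplotype distances), permutation p-values
  (individuals permuted among populations), Benjamini-Hochberg FDR, and
  the hierarchical three-level AMOVA (groups / populations / within).
- **Haplotype network**: the optimal minimum spanning network — the union
  of all minimum spanning trees of the Hamming-distance graph, with
  co-minimal alternative edges flagged.
- **Serial coalescent simulator**: backward-in-time haploid (matrilineal)
  coalescent over multiple demes with backward migration, size changes,
  divergence events, and heterochronous tips, plus HKY+Γ mutation with a
  uniform prior on the substitution rate (2–6.3% per million years) and a
  52-year generation time. Female effective sizes derive from census sizes
  as N/6 (1:1 sex ratio, 1.5:1 total:adult, Ne/N = 0.5).
- **Scenario rejection**: a 36-scenario bank (3 gene-flow timings × 4
  population structures × 3 migration rates, with whaling bottlenecks
  drawn from uniform residual-size priors) simulated at the empirical
  sampling design; a scenario is rejected when any observed pairwise
  Φ<sub>ST</sub> falls outside the 95% highest-posterior-density interval
  of its simulated distribution.
- **Duplicate screening**: multilocus probability of identity
  (PID<sub>HW</sub>, PID<sub>sib</sub>), exact/near genotype matching, and
  the Φ<sub>ST</sub> sensitivity analysis for undetected repeated
  individuals.

## Worked example

The repository is organised as an analysis project: numbered drivers under
`analysis/` run each stage on a generated study-shaped dataset (six sample
sets, 759 sequences, 370 bp) and write tables under `results/`.

```bash
cd analysis
python 01_generate_data.py
python 02_diversity.py
```

prints (seed 20120101):

```
               N   S   H     Hd  U      pi  theta_S
set
PRI           38  17  11  0.849  0  0.0148    4.046
HBFB         176  26  19  0.866  1  0.0159    4.526
BBDS          89  22  15  0.877  0  0.0165    4.348
BCB          394  30  24  0.858  5  0.0160    4.579
Okhotsk       24  14   7  0.649  0  0.0114    3.749
Spitsbergen   38  19  10  0.873  1  0.0162    4.522

26 haplotypes overall; 7 are singletons in the full dataset
Hd 95% coalescent interval, PRI: (0.549, 0.913)
```

Each row is one sample set: `N` sequences collapse into `H` distinct
haplotypes; `Hd` near 0.85 means two random whales almost always carry
different haplotypes (the high-diversity regime typical of cetacean
control regions); `pi` is the mean per-site distance between two
sequences; `theta_S` is the Watterson diversity estimate per locus.
Okhotsk, simulated as the smallest population, shows the lowest diversity.
`03_differentiation.py` then prints the pairwise matrix (Φ<sub>ST</sub>
below the diagonal, F<sub>ST</sub> above) and the AMOVA percentages;
`04_network.py` builds the haplotype network; `05_scenario_rejection.py`
compares observed Φ<sub>ST</sub> values with simulated HPD intervals for
the scenario bank; `06_duplicate_sensitivity.py` runs the repeated-
individual robustness check.

A thin CLI mirrors the drivers for ad-hoc use, e.g.:

```bash
icefloe stats --fasta PRI.fa --set PRI --ages ages.tsv
icefloe msn --fasta all.fa --set ALL -o network.tsv
icefloe scenarios
```

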