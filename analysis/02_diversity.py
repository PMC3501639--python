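"""Per-population diversity panel (N, S, H, Hd, U, pi, theta_S).

Computes the standard mtDNA summary table over the generated sample sets,
plus coalescent confidence intervals for haplotype diversity in the two
most diverse sets. Writes results/diversity.tsv.
"""

from common import RESULTS_DIR, SEED, load_dataset

from icefloe import diversity_table, hd_confidence_interval
from icefloe.popgen import singleton_haplotypes
from icefloe.seqio import collapse_haplotypes

sets = load_dataset()
table = diversity_table(sets)
table.to_csv(RESULTS_DIR / "diversity.tsv", sep="\t")
print(table.to_string())

pooled = collapse_haplotypes(sets)
print(f"\n{pooled.n_haplotypes} haplotypes overall; "
      f"{singleton_haplotypes(pooled)} are singletons in the full dataset")
for sid in ("PRI", "BCB"):
    st = next(s for s in sets if s.set_id == sid)
    lo, hi = hd_confidence_interval(st, reps=1000, seed=SEED)
    print(f"Hd 95% coalescent interval, {sid}: ({lo:.3f}, {hi:.3f})")
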