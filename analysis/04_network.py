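"""Optimal minimum spanning haplotype network.

Union of all minimum spanning trees over Hamming distances between
haplotypes, with per-population counts on the nodes. Writes
results/msn_edges.tsv and results/msn.graphml.
"""

from common import RESULTS_DIR, load_dataset

from icefloe import build_msn, collapse_haplotypes
from icefloe.network import write_edge_tsv, write_graphml

sets = load_dataset()
table = collapse_haplotypes(sets)
net = build_msn(table)
write_edge_tsv(net, RESULTS_DIR / "msn_edges.tsv")
write_graphml(net, RESULTS_DIR / "msn.graphml")
alt = sum(e.alternative for e in net.edges)
print(f"{len(net.haplotypes)} haplotypes, {len(net.edges)} network edges "
      f"({alt} alternative co-minimal edges)")
print(f"max mutational steps on an edge: {max(e.steps for e in net.edges)}")
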