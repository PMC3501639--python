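"""Optimal minimum spanning network among haplotypes.

The network is the union of all minimum spanning trees of the complete
Hamming-distance graph over haplotypes: an edge (u, v, w) belongs to some
MST exactly when u and v are not already connected using edges strictly
shorter than w (cut/cycle property). Haplotype frequencies are attached to
the nodes for rendering; they do not alter the topology.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .seqio import HaplotypeTable


@dataclass
class NetworkEdge:
    a: int
    b: int
    steps: int
    alternative: bool  # True if not part of the primary (Kruskal) MST


@dataclass
class HaplotypeNetwork:
    haplotypes: list[str]
    counts: np.ndarray  # haplotype x sample-set
    set_ids: list[str]
    edges: list[NetworkEdge]

    def total_counts(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        totals = self.total_counts()
        for i, h in enumerate(self.haplotypes):
            per_pop = {s: int(c) for s, c in zip(self.set_ids, self.counts[i])}
            g.add_node(i, haplotype=h, total=int(totals[i]), **per_pop)
        for e in self.edges:
            g.add_edge(e.a, e.b, steps=e.steps, alternative=e.alternative)
        return g


def hamming_matrix(haplotypes: list[str]) -> np.ndarray:
    """Pairwise Hamming distances between equal-length haplotype strings."""
    arr = np.array([list(h) for h in haplotypes])
    n = len(haplotypes)
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        d[i] = (arr != arr[i]).sum(axis=1)
    return d


def minimum_spanning_edges_union(d: np.ndarray) -> list[tuple[int, int, int]]:
    """All edges belonging to at least one MST of the complete graph on d."""
    n = d.shape[0]
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    iu, ju = np.triu_indices(n, k=1)
    weights = d[iu, ju]
    order = np.argsort(weights, kind="stable")
    edges: list[tuple[int, int, int]] = []
    pos = 0
    order = list(order)
    while pos < len(order):
        w = weights[order[pos]]
        batch = []
        while pos < len(order) and weights[order[pos]] == w:
            k = order[pos]
            batch.append((int(iu[k]), int(ju[k])))
            pos += 1
        # co-minimal edges: endpoints unconnected by strictly shorter edges
        keep = [(a, b) for a, b in batch if find(a) != find(b)]
        edges.extend((a, b, int(w)) for a, b in keep)
        for a, b in keep:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    return edges


def build_msn(table: HaplotypeTable) -> HaplotypeNetwork:
    """Optimal minimum spanning network for a haplotype table.

    Edges of one Kruskal MST are marked primary; co-minimal alternatives
    (edges appearing only in other MSTs) carry ``alternative=True``.
    """
    if table.n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes for a network")
    d = hamming_matrix(table.haplotypes)
    union = minimum_spanning_edges_union(d)
    g = nx.Graph()
    g.add_nodes_from(range(table.n_haplotypes))
    for a, b, w in union:
        g.add_edge(a, b, weight=w)
    primary = set()
    for a, b in nx.minimum_spanning_edges(g, data=False, algorithm="kruskal"):
        primary.add((min(a, b), max(a, b)))
    edges = [
        NetworkEdge(a=a, b=b, steps=w, alternative=(a, b) not in primary)
        for a, b, w in union
    ]
    return HaplotypeNetwork(
        haplotypes=list(table.haplotypes),
        counts=table.counts.copy(),
        set_ids=list(table.set_ids),
        edges=edges,
    )


def write_edge_tsv(network: HaplotypeNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("hap_a\thap_b\tsteps\talternative\n")
        for e in network.edges:
            fh.write(f"{e.a}\t{e.b}\t{e.steps}\t{int(e.alternative)}\n")


def write_graphml(network: HaplotypeNetwork, path) -> None:
    nx.write_graphml(network.to_networkx(), path)
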