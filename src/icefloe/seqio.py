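"""Reading, validation and collapsing of aligned mtDNA sample sets.

The unit of every downstream statistic is an :class:`AlignedSampleSet`: a
labelled collection of equal-length D-loop sequences with a per-sample
sampling age (0 for modern biopsies, >0 for archaeological material).
Haplotype bookkeeping across sample sets lives in :class:`HaplotypeTable`.
A light multilocus genotype container supports the probability-of-identity
duplicate screen applied to modern biopsy sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

VALID_CHARS = frozenset("ACGTN-")
#: IUPAC ambiguity codes other than N; rejected in strict mode.
AMBIGUITY_CHARS = frozenset("RYSWKMBDHV")

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4, "N": 5}


class RaggedAlignmentError(ValueError):
    """Raised when a record's length disagrees with the alignment."""


@dataclass
class AlignedSampleSet:
    """A labelled, aged set of equal-length aligned sequences.

    Parameters
    ----------
    set_id:
        Short population label, e.g. ``"PRI"``, ``"HBFB"``, ``"BCB"``.
    ids:
        Per-sample identifiers, unique within the set.
    seqs:
        Uppercase sequences over ``{A,C,G,T,-,N}``, all the same length.
    ages:
        Per-sample sampling age in years before present (>= 0).
    group:
        Optional higher-level stratum label ("Atlantic"/"Pacific").
    """

    set_id: str
    ids: list[str]
    seqs: list[str]
    ages: np.ndarray = None  # type: ignore[assignment]
    group: str | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError(f"duplicate sample ids in set {self.set_id!r}")
        if not self.seqs:
            raise ValueError(f"sample set {self.set_id!r} is empty")
        L = len(self.seqs[0])
        for sid, s in zip(self.ids, self.seqs):
            if len(s) != L:
                raise RaggedAlignmentError(
                    f"record {sid!r} has length {len(s)}, expected {L}"
                )
            bad = set(s) - VALID_CHARS
            if bad:
                raise ValueError(
                    f"record {sid!r} contains invalid characters {sorted(bad)}"
                )
        if self.ages is None:
            self.ages = np.zeros(len(self.ids))
        self.ages = np.asarray(self.ages, dtype=float)
        if self.ages.shape != (len(self.ids),):
            raise ValueError("ages must align with samples")
        if np.any(self.ages < 0):
            raise ValueError("sampling ages must be non-negative")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def encoded(self) -> np.ndarray:
        """Integer-encoded alignment, shape (n, length); A,C,G,T,-,N -> 0..5."""
        cached = getattr(self, "_encoded_cache", None)
        if cached is not None:
            return cached
        out = np.empty((self.n, self.length), dtype=np.int8)
        lut = np.full(128, -1, dtype=np.int8)
        for c, v in _BASE_CODE.items():
            lut[ord(c)] = v
        for i, s in enumerate(self.seqs):
            out[i] = lut[np.frombuffer(s.encode(), dtype=np.uint8)]
        self._encoded_cache = out
        return out

    def subset(self, indices: Sequence[int], set_id: str | None = None) -> "AlignedSampleSet":
        idx = list(indices)
        return AlignedSampleSet(
            set_id=set_id or self.set_id,
            ids=[self.ids[i] for i in idx],
            seqs=[self.seqs[i] for i in idx],
            ages=self.ages[idx],
            group=self.group,
        )


@dataclass
class HaplotypeTable:
    """Distinct haplotypes with per-sample-set counts.

    ``counts`` has shape (n_haplotypes, n_sets); ``site_mask`` records which
    alignment columns the haplotypes were collapsed on.
    """

    haplotypes: list[str]
    counts: np.ndarray
    set_ids: list[str]
    site_mask: np.ndarray

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def set_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def column(self, set_id: str) -> np.ndarray:
        if set_id not in self.set_ids:
            raise KeyError(f"unknown sample set {set_id!r}")
        return self.counts[:, self.set_ids.index(set_id)]


@dataclass
class GenotypeTable:
    """Multilocus genotypes; each entry an unordered allele pair or None."""

    sample_ids: list[str]
    genotypes: list[list[tuple[int, int] | None]]
    locus_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genotypes:
            raise ValueError("empty genotype table")
        n_loci = len(self.genotypes[0])
        for sid, row in zip(self.sample_ids, self.genotypes):
            if len(row) != n_loci:
                raise ValueError(f"sample {sid!r} has wrong locus count")
        if not self.locus_names:
            self.locus_names = [f"L{i+1}" for i in range(n_loci)]

    @property
    def n_loci(self) -> int:
        return len(self.genotypes[0])


def read_fasta(
    path,
    set_id: str,
    age_spec: float | Mapping[str, float] = 0.0,
    group: str | None = None,
    map_ambiguous: bool = False,
) -> AlignedSampleSet:
    """Read an aligned FASTA into an :class:`AlignedSampleSet`.

    ``age_spec`` is either a scalar age (years before present) applied to all
    samples or a mapping ``sample_id -> age``. Sequences are uppercased;
    IUPAC ambiguity codes other than N raise unless ``map_ambiguous`` is set,
    in which case they are converted to N.
    """
    ids: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        if map_ambiguous:
            s = "".join("N" if c in AMBIGUITY_CHARS else c for c in s)
        ids.append(rec.id)
        seqs.append(s)
    if not ids:
        raise ValueError(f"no FASTA records found in {path}")
    if isinstance(age_spec, Mapping):
        missing = [i for i in ids if i not in age_spec]
        if missing:
            raise KeyError(f"ages missing for samples {missing}")
        ages = np.array([float(age_spec[i]) for i in ids])
    else:
        ages = np.full(len(ids), float(age_spec))
    return AlignedSampleSet(set_id=set_id, ids=ids, seqs=seqs, ages=ages, group=group)


def read_ages_tsv(path) -> dict[str, float]:
    """Two-column TSV (sample_id, age_years) -> mapping."""
    ages: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sid, age = line.split("\t")[:2]
            ages[sid] = float(age)
    return ages


def complete_deletion_mask(sets: Iterable[AlignedSampleSet]) -> np.ndarray:
    """Boolean mask of columns free of '-'/'N' across the pooled alignment."""
    sets = list(sets)
    L = sets[0].length
    mask = np.ones(L, dtype=bool)
    for st in sets:
        enc = st.encoded()
        mask &= ~np.any(enc >= 4, axis=0)
    return mask


def collapse_haplotypes(
    sets: Sequence[AlignedSampleSet], site_policy: str = "complete"
) -> HaplotypeTable:
    """Collapse identical sequences (on retained sites) into haplotypes.

    ``site_policy='complete'`` drops every column containing '-' or 'N'
    anywhere in the pooled alignment (DnaSP-style complete deletion), the
    fixed-mask convention needed for reproducible S and H. ``'all'`` keeps
    every column.
    """
    if not sets:
        raise ValueError("no sample sets given")
    L = sets[0].length
    for st in sets:
        if st.length != L:
            raise RaggedAlignmentError(
                f"set {st.set_id!r} has length {st.length}, expected {L}"
            )
    if site_policy == "complete":
        mask = complete_deletion_mask(sets)
    elif site_policy == "all":
        mask = np.ones(L, dtype=bool)
    else:
        raise ValueError(f"unknown site_policy {site_policy!r}")
    if not mask.any():
        raise ValueError("no sites retained under the site policy")
    keep = np.flatnonzero(mask)
    hap_index: dict[str, int] = {}
    haplotypes: list[str] = []
    counts_rows: list[list[int]] = []
    for k, st in enumerate(sets):
        for s in st.seqs:
            h = "".join(s[j] for j in keep)
            if h not in hap_index:
                hap_index[h] = len(haplotypes)
                haplotypes.append(h)
                counts_rows.append([0] * len(sets))
            counts_rows[hap_index[h]][k] += 1
    counts = np.array(counts_rows, dtype=int)
    return HaplotypeTable(
        haplotypes=haplotypes,
        counts=counts,
        set_ids=[st.set_id for st in sets],
        site_mask=mask,
    )


def _locus_frequencies(g: GenotypeTable, locus: int) -> np.ndarray | None:
    alleles: list[int] = []
    for row in g.genotypes:
        entry = row[locus]
        if entry is not None:
            alleles.extend(entry)
    if not alleles:
        return None
    vals, cnts = np.unique(alleles, return_counts=True)
    return cnts / cnts.sum()


def probability_of_identity(g: GenotypeTable) -> tuple[float, float]:
    """Multilocus probability of identity, unbiased and full-sib variants.

    Per locus, with allele frequencies ``p_i``::

        PID_HW  = sum_i p_i^4 + sum_{i<j} (2 p_i p_j)^2
        PID_sib = 0.25 + 0.5*sum p_i^2 + 0.5*(sum p_i^2)^2 - 0.25*sum p_i^4

    multiplied across loci. Loci with no observed genotypes are excluded
    with a warning.
    """
    pid_hw = 1.0
    pid_sib = 1.0
    used = 0
    for locus in range(g.n_loci):
        p = _locus_frequencies(g, locus)
        if p is None:
            warnings.warn(
                f"locus {g.locus_names[locus]!r} has no observations; excluded"
            )
            continue
        s2 = float(np.sum(p**2))
        s4 = float(np.sum(p**4))
        # sum_{i<j} (2 p_i p_j)^2 = 2 * ((sum p^2)^2 - sum p^4)
        hw = s4 + 2 * (s2**2 - s4)
        sib = 0.25 + 0.5 * s2 + 0.5 * s2**2 - 0.25 * s4
        pid_hw *= hw
        pid_sib *= sib
        used += 1
    if used == 0:
        raise ValueError("no locus with observations")
    return pid_hw, pid_sib


def find_duplicates(
    g: GenotypeTable, mismatch_tolerance: int = 2
) -> tuple[list[tuple[str, str]], list[tuple[str, str, int]]]:
    """Exact-match pairs and near-match pairs (<= tolerance mismatching loci).

    Loci missing in either sample are ignored for that pair. Returns
    ``(exact_pairs, flagged_pairs)``; flagged pairs carry the mismatch count
    (1..tolerance) and exclude exact matches.
    """
    if mismatch_tolerance not in (0, 1, 2):
        raise ValueError("mismatch_tolerance must be 0, 1 or 2")
    exact: list[tuple[str, str]] = []
    flagged: list[tuple[str, str, int]] = []
    n = len(g.sample_ids)
    for a in range(n):
        for b in range(a + 1, n):
            mism = 0
            compared = 0
            for la, lb in zip(g.genotypes[a], g.genotypes[b]):
                if la is None or lb is None:
                    continue
                compared += 1
                if tuple(sorted(la)) != tuple(sorted(lb)):
                    mism += 1
                    if mism > mismatch_tolerance:
                        break
            if compared == 0:
                continue
            if mism == 0:
                exact.append((g.sample_ids[a], g.sample_ids[b]))
            elif mism <= mismatch_tolerance:
                flagged.append((g.sample_ids[a], g.sample_ids[b], mism))
    return exact, flagged


def write_fasta(sample_set: AlignedSampleSet, path) -> None:
    with open(path, "w") as fh:
        for sid, s in zip(sample_set.ids, sample_set.seqs):
            fh.write(f">{sid}\n{s}\n")
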