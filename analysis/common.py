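"""Shared IO for the analysis drivers: dataset location and loading."""

from __future__ import annotations

import pathlib

import numpy as np

from icefloe import SyntheticDesign, generate_study_like, read_fasta
from icefloe.seqio import read_ages_tsv, write_fasta

ROOT = pathlib.Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "results" / "data"
RESULTS_DIR = ROOT / "results"

SET_ORDER = ["PRI", "HBFB", "BBDS", "BCB", "Okhotsk", "Spitsbergen"]
GROUPS = {"Atlantic": ["HBFB", "BBDS", "Spitsbergen"],
          "Pacific": ["PRI", "BCB", "Okhotsk"]}
SEED = 20120101


def generate_dataset(seed: int = SEED, scale: float = 1.0):
    """Generate the study-shaped dataset and write it under results/data."""
    rng = np.random.default_rng(seed)
    sets = generate_study_like(SyntheticDesign(scale=scale), rng)
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    for st in sets:
        write_fasta(st, DATA_DIR / f"{st.set_id}.fa")
        with open(DATA_DIR / f"{st.set_id}.ages.tsv", "w") as fh:
            for sid, age in zip(st.ids, st.ages):
                fh.write(f"{sid}\t{age:.1f}\n")
    return sets


def load_dataset():
    """Load the generated dataset, creating it first if absent."""
    if not (DATA_DIR / "PRI.fa").exists():
        return generate_dataset()
    sets = []
    for sid in SET_ORDER:
        ages = read_ages_tsv(DATA_DIR / f"{sid}.ages.tsv")
        sets.append(read_fasta(DATA_DIR / f"{sid}.fa", set_id=sid, age_spec=ages))
    return sets
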