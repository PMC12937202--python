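import random
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from snap_pcr.seqio import SequenceRecord, SpeciesAlignment


@pytest.fixture
def toy_alignment() -> SpeciesAlignment:
    """Three species, eight columns; diagnostic structure known by hand:

    A: ACGTACGT x2, B: ACGAACGT x2, C: ACGCACGA.
    Columns 1-3 and 5-7 conserved; col 4 diagnostic for A (T) and C (C);
    col 8 diagnostic for C (A).
    """
    return SpeciesAlignment(
        records=(
            SequenceRecord(id="a1", residues="ACGTACGT", species="A"),
            SequenceRecord(id="a2", residues="ACGTACGT", species="A"),
            SequenceRecord(id="b1", residues="ACGAACGT", species="B"),
            SequenceRecord(id="b2", residues="ACGAACGT", species="B"),
            SequenceRecord(id="c1", residues="ACGCACGA", species="C"),
        )
    )


def random_alignment(rng: random.Random, max_species=5, max_records=12, max_cols=60):
    """Small random species-labelled alignment (may contain gaps and
    ambiguity codes at low rate)."""
    n_species = rng.randint(2, max_species)
    n_cols = rng.randint(4, max_cols)
    records = []
    symbols = "ACGT"
    rid = 0
    for s in range(n_species):
        n_recs = rng.randint(1, max(1, max_records // n_species))
        base = [rng.choice(symbols) for _ in range(n_cols)]
        for _ in range(n_recs):
            seq = list(base)
            for i in range(n_cols):
                r = rng.random()
                if r < 0.08:
                    seq[i] = rng.choice(symbols)
                elif r < 0.10:
                    seq[i] = rng.choice("RYSWKMN")
                elif r < 0.12:
                    seq[i] = "-"
            rid += 1
            records.append(
                SequenceRecord(id=f"r{rid}", residues="".join(seq), species=f"sp{s}")
            )
    return SpeciesAlignment(records=tuple(records))
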