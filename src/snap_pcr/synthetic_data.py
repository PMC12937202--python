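"""Synthetic species-labelled alignments with planted ground truth.

Generates K-species alignments containing one planted pan-species conserved
window (forward-primer real estate), per-species clusters of planted
diagnostic SNPs (reverse-primer anchors at increasing distances from the
window, so a size ladder exists by construction), optional background
interspecific divergence, and optional intraspecific haplotype noise that
never touches planted columns.  Everything is driven by a single seeded
PRNG, so identical specs yield byte-identical alignments.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .seqio import SequenceRecord, SpeciesAlignment

__all__ = [
    "SyntheticPanelSpec",
    "PanelTruth",
    "generate_species_panel",
    "spike_intraspecific_variants",
]

_BASES = "ACGT"
#: spacing between planted diagnostic columns within one species' cluster
_DIAG_SPACING = 3


@dataclass(frozen=True)
class SyntheticPanelSpec:
    n_species: int = 5
    haplotypes_per_species: int = 6
    length: int = 700
    n_diag_per_species: int = 8
    conserved_window: tuple[int, int] = (100, 30)  # (start column, width)
    background_divergence: float = 0.0
    intraspecific_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need >= 2 species")
        if self.haplotypes_per_species < 1 or self.n_diag_per_species < 1:
            raise ValueError("counts must be >= 1")
        for p in (self.background_divergence, self.intraspecific_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0,1]")
        ws, wl = self.conserved_window
        if ws < 1 or wl < 1 or ws + wl - 1 > self.length:
            raise ValueError("conserved window does not fit in the alignment")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(f"sp{i + 1:02d}" for i in range(self.n_species))

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticPanelSpec":
        d = dict(d)
        if "conserved_window" in d:
            d["conserved_window"] = tuple(d["conserved_window"])
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass(frozen=True)
class PanelTruth:
    """Planted ground truth accompanying a synthetic alignment."""

    diag_sites_by_species: Mapping[str, tuple[tuple[int, str], ...]]
    conserved_windows: tuple[tuple[int, int], ...]

    def protected_columns(self) -> frozenset[int]:
        cols: set[int] = set()
        for sites in self.diag_sites_by_species.values():
            cols.update(col for col, _ in sites)
        for start, end in self.conserved_windows:
            cols.update(range(start, end + 1))
        return frozenset(cols)


def _plan_layout(spec: SyntheticPanelSpec) -> dict[str, list[int]]:
    """Deterministic placement of each species' diagnostic-column cluster
    downstream of the conserved window, clusters evenly spread so amplicon
    sizes ladder."""
    ws, wl = spec.conserved_window
    window_end = ws + wl - 1
    cluster_span = (spec.n_diag_per_species - 1) * _DIAG_SPACING + 1
    # leave room between window and first cluster so the shortest amplicon
    # still clears typical min_amplicon settings when the forward primer is
    # confined to the planted window
    region_start = window_end + 50
    region_end = spec.length - 5
    if spec.n_species == 1:
        step = 0
    else:
        step = (region_end - region_start - cluster_span) // (spec.n_species - 1)
    if step < cluster_span + 1 and spec.n_species > 1:
        raise ValueError(
            "alignment too short for non-overlapping diagnostic clusters; "
            f"need roughly {region_start + (spec.n_species - 1) * (cluster_span + 2) + cluster_span + 5} columns"
        )
    layout: dict[str, list[int]] = {}
    for i, sp in enumerate(spec.species):
        start = region_start + i * step
        layout[sp] = [start + j * _DIAG_SPACING for j in range(spec.n_diag_per_species)]
        if layout[sp][-1] > spec.length:
            raise ValueError("diagnostic cluster overflows the alignment")
    return layout


def generate_species_panel(
    spec: SyntheticPanelSpec,
) -> tuple[SpeciesAlignment, PanelTruth]:
    """Generate an alignment plus its :class:`PanelTruth` (same seed, same bytes)."""
    layout = _plan_layout(spec)
    rng = random.Random(spec.seed)
    ws, wl = spec.conserved_window
    window = (ws, ws + wl - 1)
    all_diag_cols = {c for cols in layout.values() for c in cols}

    backbone = [rng.choice(_BASES) for _ in range(spec.length)]

    def balanced(n: int) -> list[str]:
        # shuffled balanced multiset: ~50% GC without periodicity, so primer
        # QC windows (GC/Tm) are satisfiable by construction; reject shuffles
        # with homopolymer runs long enough to trip QC filters
        pool = list(_BASES) * ((n + 3) // 4)
        for _ in range(100):
            rng.shuffle(pool)
            run = best = 1
            for a, b in zip(pool, pool[1:n]):
                run = run + 1 if a == b else 1
                best = max(best, run)
            if best <= 3:
                break
        return pool[:n]

    # balanced composition inside the conserved window and around each
    # diagnostic cluster (where reverse-primer footprints will sit)
    backbone[window[0] - 1 : window[1]] = balanced(window[1] - window[0] + 1)
    for cols in layout.values():
        lo, hi = cols[0], min(spec.length, cols[-1] + 25)
        backbone[lo - 1 : hi] = balanced(hi - lo + 1)
    # species-level allele matrix, started from the shared backbone
    alleles = {sp: list(backbone) for sp in spec.species}

    truth_sites: dict[str, list[tuple[int, str]]] = {sp: [] for sp in spec.species}
    for sp in spec.species:
        for col in layout[sp]:
            shared = backbone[col - 1]
            options = [b for b in _BASES if b != shared]
            rng.shuffle(options)
            # prefer a variant that does not extend a homopolymer run
            neighbours = {
                alleles[sp][col - 2] if col >= 2 else "",
                alleles[sp][col] if col < spec.length else "",
            }
            options.sort(key=lambda b: b in neighbours)
            variant = options[0]
            alleles[sp][col - 1] = variant
            truth_sites[sp].append((col, variant))

    if spec.background_divergence > 0:
        for col in range(1, spec.length + 1):
            if window[0] <= col <= window[1] or col in all_diag_cols:
                continue
            if rng.random() < spec.background_divergence:
                sp = rng.choice(spec.species)
                current = alleles[sp][col - 1]
                alleles[sp][col - 1] = rng.choice([b for b in _BASES if b != current])

    records: list[SequenceRecord] = []
    for sp in spec.species:
        for h in range(spec.haplotypes_per_species):
            residues = list(alleles[sp])
            if spec.intraspecific_rate > 0:
                for col in range(1, spec.length + 1):
                    if window[0] <= col <= window[1] or col in all_diag_cols:
                        continue
                    if rng.random() < spec.intraspecific_rate:
                        cur = residues[col - 1]
                        residues[col - 1] = rng.choice([b for b in _BASES if b != cur])
            records.append(
                SequenceRecord(
                    id=f"{sp}_h{h + 1}", residues="".join(residues), species=sp
                )
            )

    aln = SpeciesAlignment(records=tuple(records))
    truth = PanelTruth(
        diag_sites_by_species={sp: tuple(v) for sp, v in truth_sites.items()},
        conserved_windows=(window,),
    )
    return aln, truth


def spike_intraspecific_variants(
    aln: SpeciesAlignment, truth: PanelTruth, rate: float, seed: int
) -> SpeciesAlignment:
    """Add per-haplotype substitutions outside all planted columns.

    ``rate=0`` returns an alignment with identical residues; planted truth
    remains valid for any rate.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0,1]")
    if rate == 0.0:
        return aln
    protected = truth.protected_columns()
    rng = random.Random(seed)
    new_records: list[SequenceRecord] = []
    for rec in aln.records:
        residues = list(rec.residues)
        for col in range(1, len(residues) + 1):
            if col in protected or residues[col - 1] not in _BASES:
                continue
            if rng.random() < rate:
                cur = residues[col - 1]
                residues[col - 1] = rng.choice([b for b in _BASES if b != cur])
        new_records.append(
            SequenceRecord(
                id=rec.id,
                residues="".join(residues),
                species=rec.species,
                description=rec.description,
            )
        )
    return SpeciesAlignment(records=tuple(new_records))
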