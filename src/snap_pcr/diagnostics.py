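"""Diagnostic-SNP and conserved-window discovery on species-labelled alignments.

A column is *diagnostic* for a target species when the target is fixed for a
single unambiguous base that no other species carries at that column, and no
record has a gap there.  Ambiguity codes in the target disqualify a column;
ambiguity codes in non-target species count as carrying every base they
encode (conservative: avoids false diagnostic calls).  Conserved columns
carry one identical unambiguous base in every record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .seqio import GAP, IUPAC_SETS, SpeciesAlignment, is_unambiguous

__all__ = [
    "ColumnProfile",
    "DiagnosticSite",
    "build_column_profiles",
    "find_diagnostic_sites",
    "find_conserved_windows",
]


@dataclass(frozen=True)
class ColumnProfile:
    """Per-column summary of a species alignment (1-based column)."""

    column: int
    alleles_by_species: Mapping[str, frozenset[str]]
    has_gap: bool
    conserved_all: bool


@dataclass(frozen=True)
class DiagnosticSite:
    """Column where the target species' fixed allele is absent elsewhere."""

    column: int
    target_species: str
    target_allele: str
    other_alleles: Mapping[str, frozenset[str]]


def build_column_profiles(aln: SpeciesAlignment) -> list[ColumnProfile]:
    """One :class:`ColumnProfile` per alignment column, in column order."""
    profiles: list[ColumnProfile] = []
    by_species = {sp: aln.records_for(sp) for sp in aln.species}
    for col in range(1, aln.length + 1):
        alleles: dict[str, frozenset[str]] = {}
        has_gap = False
        observed: set[str] = set()
        for sp, recs in by_species.items():
            symbols = set()
            for rec in recs:
                ch = rec.residues[col - 1]
                if ch == GAP:
                    has_gap = True
                else:
                    symbols.add(ch)
            alleles[sp] = frozenset(symbols)
            observed |= symbols
        conserved = (
            not has_gap
            and len(observed) == 1
            and is_unambiguous(next(iter(observed)))
        )
        profiles.append(
            ColumnProfile(
                column=col,
                alleles_by_species=alleles,
                has_gap=has_gap,
                conserved_all=conserved,
            )
        )
    return profiles


def _expand(symbols: frozenset[str]) -> frozenset[str]:
    """Expand ambiguity codes to the full base set they encode."""
    out: set[str] = set()
    for s in symbols:
        out |= IUPAC_SETS[s]
    return frozenset(out)


def find_diagnostic_sites(
    profiles: Sequence[ColumnProfile], target: str
) -> list[DiagnosticSite]:
    """All columns diagnostic for ``target``, sorted by column."""
    if not profiles:
        return []
    if target not in profiles[0].alleles_by_species:
        raise KeyError(f"unknown species {target!r}")
    sites: list[DiagnosticSite] = []
    for prof in profiles:
        if prof.has_gap:
            continue
        target_set = prof.alleles_by_species[target]
        if len(target_set) != 1:
            continue
        allele = next(iter(target_set))
        if not is_unambiguous(allele):
            continue
        others = {
            sp: symbols
            for sp, symbols in prof.alleles_by_species.items()
            if sp != target
        }
        if any(allele in _expand(symbols) for symbols in others.values()):
            continue
        sites.append(
            DiagnosticSite(
                column=prof.column,
                target_species=target,
                target_allele=allele,
                other_alleles=others,
            )
        )
    return sites


def find_conserved_windows(
    profiles: Sequence[ColumnProfile], min_len: int
) -> list[tuple[int, int]]:
    """Maximal runs of conserved columns of length >= ``min_len``.

    Returns 1-based inclusive ``(start, end)`` intervals, sorted.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    windows: list[tuple[int, int]] = []
    run_start: int | None = None
    for prof in profiles:
        if prof.conserved_all:
            if run_start is None:
                run_start = prof.column
        else:
            if run_start is not None:
                if prof.column - run_start >= min_len:
                    windows.append((run_start, prof.column - 1))
                run_start = None
    if run_start is not None and profiles[-1].column - run_start + 1 >= min_len:
        windows.append((run_start, profiles[-1].column))
    return windows
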