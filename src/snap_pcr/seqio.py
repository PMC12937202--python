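"""Sequence and alignment I/O with IUPAC-aware primitives.

Reads FASTA files into species-labelled records, normalises residues to a
single canonical alphabet (upper case, U -> T), and provides the small
nucleotide-symbol algebra (reverse complement, ambiguity compatibility)
that every downstream stage relies on.

Coordinate convention: alignment columns are 1-based and inclusive
throughout the package.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "SequenceRecord",
    "SpeciesAlignment",
    "SeqIOError",
    "IUPAC_SETS",
    "GAP",
    "read_fasta",
    "write_fasta",
    "read_species_map",
    "revcomp",
    "iupac_compatible",
    "ungap",
]

GAP = "-"

#: Base sets encoded by each IUPAC nucleotide symbol.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_UNAMBIGUOUS = frozenset("ACGT")
_LEGAL = frozenset(IUPAC_SETS) | {GAP}


class SeqIOError(ValueError):
    """Raised for malformed sequence input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One nucleotide sequence with an optional species label."""

    id: str
    residues: str
    species: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("record id must be non-empty")
        if not self.residues:
            raise SeqIOError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in _LEGAL:
                raise SeqIOError(
                    f"record {self.id!r}: illegal character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SpeciesAlignment:
    """An aligned, species-labelled set of records (1-based columns)."""

    records: tuple[SequenceRecord, ...]
    species_index: Mapping[str, tuple[str, ...]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.records:
            raise SeqIOError("alignment has no records")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise SeqIOError(f"records have unequal lengths: {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise SeqIOError("duplicate record ids in alignment")
        for r in self.records:
            if not r.species:
                raise SeqIOError(f"record {r.id!r} has no species label")
        index: dict[str, list[str]] = {}
        for r in self.records:
            index.setdefault(r.species, []).append(r.id)
        if len(index) < 2:
            raise SeqIOError("alignment must contain at least 2 species")
        object.__setattr__(
            self, "species_index", {sp: tuple(v) for sp, v in index.items()}
        )

    @property
    def length(self) -> int:
        return len(self.records[0])

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.species_index)

    def records_for(self, species: str) -> tuple[SequenceRecord, ...]:
        if species not in self.species_index:
            raise KeyError(f"unknown species {species!r}")
        wanted = set(self.species_index[species])
        return tuple(r for r in self.records if r.id in wanted)

    def column(self, col: int) -> str:
        """Residues of 1-based column ``col``, in record order."""
        if not 1 <= col <= self.length:
            raise IndexError(f"column {col} outside 1..{self.length}")
        return "".join(r.residues[col - 1] for r in self.records)


def _normalise(raw: str, rec_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    for pos, ch in enumerate(seq, start=1):
        if ch not in _LEGAL:
            raise SeqIOError(
                f"record {rec_id!r}: illegal character {ch!r} at position {pos}"
            )
    return seq


def _parse_header(line: str) -> tuple[str, str, str]:
    body = line[1:].strip()
    if not body:
        raise SeqIOError("FASTA header with empty id")
    parts = body.split(None, 1)
    rec_id = parts[0]
    description = parts[1] if len(parts) > 1 else ""
    species = ""
    for token in description.split():
        if token.startswith("species="):
            species = token[len("species="):]
    return rec_id, species, description


def read_fasta(
    path: str | Path | io.TextIOBase,
    species_map: Mapping[str, str] | None = None,
) -> list[SequenceRecord]:
    """Parse a FASTA file into :class:`SequenceRecord` objects.

    Species labels are taken from ``species_map`` when given, else from a
    ``species=`` token in the header description, else left empty.
    Residues are upper-cased and U is normalised to T.
    """
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
        src = "<stream>"
    else:
        lines = Path(path).read_text().splitlines()
        src = str(path)

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    rec_id: str | None = None
    species = description = ""
    chunks: list[str] = []

    def flush() -> None:
        nonlocal rec_id
        if rec_id is None:
            return
        seq = _normalise("".join(chunks), rec_id)
        sp = species
        if species_map is not None:
            if rec_id not in species_map:
                raise SeqIOError(f"{src}: record {rec_id!r} missing from species map")
            sp = species_map[rec_id]
        records.append(
            SequenceRecord(id=rec_id, residues=seq, species=sp, description=description)
        )
        rec_id = None

    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            flush()
            rec_id, species, description = _parse_header(stripped)
            if rec_id in seen:
                raise SeqIOError(f"{src}: duplicate record id {rec_id!r} at line {lineno}")
            seen.add(rec_id)
            chunks = []
        else:
            if rec_id is None:
                raise SeqIOError(f"{src}: sequence data before any header at line {lineno}")
            chunks.append(stripped)
    flush()
    if not records:
        raise SeqIOError(f"{src}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA; headers are re-serialised canonically."""
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.species:
                header += f" species={rec.species}"
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_species_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``record_id<TAB>species``."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise SeqIOError(f"{path}: malformed species-map line {lineno}: {line!r}")
        if parts[0] in mapping:
            raise SeqIOError(f"{path}: duplicate record id {parts[0]!r} at line {lineno}")
        mapping[parts[0]] = parts[1]
    return mapping


def alignment_from_fasta(
    path: str | Path,
    species_map_path: str | Path | None = None,
) -> SpeciesAlignment:
    """Convenience loader: FASTA (+ optional TSV species map) -> alignment."""
    smap = read_species_map(species_map_path) if species_map_path else None
    return SpeciesAlignment(records=tuple(read_fasta(path, species_map=smap)))


def revcomp(seq: str) -> str:
    """Reverse complement of an ungapped IUPAC nucleotide string."""
    out = []
    for pos, ch in enumerate(seq, start=1):
        comp = _COMPLEMENT.get(ch)
        if comp is None:
            raise SeqIOError(f"illegal or gapped character {ch!r} at position {pos}")
        out.append(comp)
    return "".join(reversed(out))


def iupac_compatible(a: str, b: str) -> bool:
    """True iff the base sets encoded by two IUPAC symbols intersect."""
    try:
        sa, sb = IUPAC_SETS[a], IUPAC_SETS[b]
    except KeyError as exc:
        raise SeqIOError(f"not an IUPAC nucleotide symbol: {exc.args[0]!r}") from exc
    return bool(sa & sb)


def is_unambiguous(symbol: str) -> bool:
    return symbol in _UNAMBIGUOUS


def ungap(seq: str) -> str:
    return seq.replace(GAP, "")
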