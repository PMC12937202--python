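"""Primer and multiplex-panel design.

Designs a universal forward primer inside a pan-species conserved window and
per-species reverse primers whose 3' terminus sits on a diagnostic SNP of the
target species, then assembles a panel whose amplicon sizes form a resolvable
ladder.

Reverse primers are the reverse complement of the *target* species' consensus
footprint: they match the target perfectly and mismatch every non-target at
the diagnostic columns, which is what blocks extension on non-targets.
Amplicon sizes are measured on gap-stripped target coordinates (physical
template lengths), not raw alignment columns.

Nearest-neighbor melting temperatures use the unified SantaLucia-2004
parameter set with the 0.368*(N-1)*ln[Na+] entropic salt correction; the
duplex-concentration term uses the total single-strand concentration.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .diagnostics import DiagnosticSite
from .seqio import GAP, SpeciesAlignment, is_unambiguous, revcomp

__all__ = [
    "Primer",
    "PrimerPanel",
    "DesignConfig",
    "PanelInfeasibleError",
    "gc_content",
    "tm_wallace",
    "tm_nearest_neighbor",
    "species_consensus",
    "design_universal_forward",
    "design_species_reverse",
    "dimer_score",
    "assemble_panel",
    "panel_to_json",
    "panel_from_json",
    "panel_to_tsv",
    "panel_from_tsv",
]

UNIVERSAL = "universal"


def gc_content(seq: str) -> float:
    """(#G + #C) / length for an unambiguous, ungapped sequence."""
    _check_unambiguous(seq)
    return (seq.count("G") + seq.count("C")) / len(seq)


def tm_wallace(seq: str) -> float:
    """Wallace-rule melting temperature: 2*(A+T) + 4*(G+C) degrees C."""
    _check_unambiguous(seq)
    at = seq.count("A") + seq.count("T")
    gc = seq.count("G") + seq.count("C")
    return 2.0 * at + 4.0 * gc


def _check_unambiguous(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"sequence contains ambiguous or gap characters: {sorted(bad)}")


# Unified nearest-neighbor parameters (SantaLucia & Hicks 2004).
# (delta_H kcal/mol, delta_S cal/mol/K) per 5'->3' stack on the top strand.
_NN_STACKS: dict[str, tuple[float, float]] = {
    "AA": (-7.6, -21.3), "TT": (-7.6, -21.3),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_NN_INIT = (0.2, -5.7)
_NN_TERM_AT = (2.2, 6.9)
_GAS_CONSTANT = 1.987  # cal / (mol K)


def tm_nearest_neighbor(seq: str, na_mM: float = 50.0, oligo_nM: float = 250.0) -> float:
    """Nearest-neighbor Tm (degrees C) under the unified parameter set.

    Monotone non-decreasing in ``na_mM``; requires length >= 8.
    """
    _check_unambiguous(seq)
    if len(seq) < 8:
        raise ValueError(f"sequence too short for NN model: {len(seq)} < 8")
    if na_mM <= 0 or oligo_nM <= 0:
        raise ValueError("concentrations must be positive")
    dh, ds = _NN_INIT
    for terminal in (seq[0], seq[-1]):
        if terminal in "AT":
            dh += _NN_TERM_AT[0]
            ds += _NN_TERM_AT[1]
    for i in range(len(seq) - 1):
        h, s = _NN_STACKS[seq[i : i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    k = oligo_nM * 1e-9
    return (1000.0 * dh) / (ds + _GAS_CONSTANT * math.log(k)) - 273.15


def max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


@dataclass(frozen=True)
class Primer:
    """An oriented oligo, optionally anchored to alignment columns.

    ``footprint`` is the 1-based inclusive alignment-column interval the
    primer covers; for reverse primers it is the plus-strand region whose
    reverse complement is the primer, so the primer's 3' base pairs the
    column at ``footprint[0]``.  ``diagnostic_offsets`` are 0-based distances
    from the 3' terminus to diagnostic columns inside the footprint.
    """

    name: str
    sequence: str
    orientation: str  # "forward" | "reverse"
    target_species: str = UNIVERSAL
    footprint: tuple[int, int] | None = None
    tm_wallace: float = 0.0
    tm_nn: float = 0.0
    gc: float = 0.0
    diagnostic_offsets: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.footprint is not None:
            start, end = self.footprint
            if end - start + 1 != len(self.sequence):
                raise ValueError(
                    f"primer {self.name!r}: footprint span {start}..{end} "
                    f"!= sequence length {len(self.sequence)}"
                )
        if self.diagnostic_offsets and self.orientation == "reverse":
            if 0 not in self.diagnostic_offsets:
                raise ValueError(
                    f"reverse primer {self.name!r} lacks a 3'-terminal diagnostic site"
                )
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc out of [0,1]")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DesignConfig:
    """Numeric design constraints (defaults admit typical barcode primers)."""

    primer_len_min: int = 18
    primer_len_max: int = 25
    tm_min: float = 56.0
    tm_max: float = 66.0
    max_tm_spread: float = 10.0
    gc_min: float = 0.30
    gc_max: float = 0.65
    max_homopolymer: int = 4
    min_diag_in_footprint: int = 1
    require_3prime_anchor: bool = True
    min_separation: int = 25
    min_amplicon: int = 80
    max_amplicon: int = 1000
    dimer_threshold: int = 8

    def __post_init__(self) -> None:
        if self.primer_len_min > self.primer_len_max:
            raise ValueError("empty primer length range")
        if self.tm_min > self.tm_max or self.gc_min > self.gc_max:
            raise ValueError("empty Tm or GC range")
        if self.min_separation <= 0:
            raise ValueError("min_separation must be > 0")

    @property
    def tm_mid(self) -> float:
        return (self.tm_min + self.tm_max) / 2.0

    @classmethod
    def from_dict(cls, d: Mapping) -> "DesignConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass(frozen=True)
class PrimerPanel:
    """One universal forward + per-species reverse primers + size ladder."""

    forward: Primer
    reverses: Mapping[str, Primer]
    expected_sizes: Mapping[str, int]
    min_separation: int

    def __post_init__(self) -> None:
        if set(self.reverses) != set(self.expected_sizes):
            raise ValueError("reverses and expected_sizes must cover the same species")
        sizes = sorted(self.expected_sizes.values())
        for a, b in zip(sizes, sizes[1:]):
            if b - a < self.min_separation:
                raise ValueError(
                    f"amplicon sizes {a} and {b} closer than min_separation "
                    f"{self.min_separation}"
                )
        if self.forward.footprint is not None:
            for sp, rev in self.reverses.items():
                if rev.footprint is not None and rev.footprint[0] <= self.forward.footprint[1]:
                    raise ValueError(
                        f"reverse footprint for {sp!r} not 3' of the forward footprint"
                    )

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted(self.reverses))


class PanelInfeasibleError(RuntimeError):
    """No primer combination satisfies the panel constraints."""

    def __init__(self, constraint: str, detail: str):
        super().__init__(f"panel infeasible: {constraint}: {detail}")
        self.constraint = constraint
        self.detail = detail

    def to_dict(self) -> dict:
        return {"infeasible": True, "constraint": self.constraint, "detail": self.detail}


def species_consensus(aln: SpeciesAlignment, species: str) -> str:
    """Majority consensus of one species' records, gaps preserved.

    A column where any record of the species is gapped yields a gap; a column
    with no unambiguous majority base yields ``N`` (which design filters
    reject).  Ties break alphabetically for determinism.
    """
    recs = aln.records_for(species)
    out: list[str] = []
    for col in range(aln.length):
        symbols = [r.residues[col] for r in recs]
        if GAP in symbols:
            out.append(GAP)
            continue
        counts: dict[str, int] = {}
        for s in symbols:
            if is_unambiguous(s):
                counts[s] = counts.get(s, 0) + 1
        if not counts:
            out.append("N")
            continue
        best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        out.append(best)
    return "".join(out)


def _passes_qc(seq: str, cfg: DesignConfig) -> bool:
    if set(seq) - set("ACGT"):
        return False
    if not cfg.gc_min <= gc_content(seq) <= cfg.gc_max:
        return False
    if not cfg.tm_min <= tm_wallace(seq) <= cfg.tm_max:
        return False
    if max_homopolymer(seq) > cfg.max_homopolymer:
        return False
    return True


def design_universal_forward(
    aln: SpeciesAlignment,
    windows: Sequence[tuple[int, int]],
    cfg: DesignConfig,
) -> list[Primer]:
    """All admissible forward primers inside pan-species conserved windows.

    Ranked by |Wallace Tm - midpoint of the Tm range|, ties broken by leftmost
    footprint then shortest length.
    """
    template = aln.records[0].residues  # conserved windows are identical across records
    candidates: list[Primer] = []
    for (wstart, wend) in windows:
        for start in range(wstart, wend + 1):
            for length in range(cfg.primer_len_min, cfg.primer_len_max + 1):
                end = start + length - 1
                if end > wend:
                    break
                seq = template[start - 1 : end]
                if not _passes_qc(seq, cfg):
                    continue
                candidates.append(
                    Primer(
                        name=f"F_{start}_{end}",
                        sequence=seq,
                        orientation="forward",
                        target_species=UNIVERSAL,
                        footprint=(start, end),
                        tm_wallace=tm_wallace(seq),
                        tm_nn=tm_nearest_neighbor(seq) if len(seq) >= 8 else float("nan"),
                        gc=gc_content(seq),
                    )
                )
    candidates.sort(key=lambda p: (abs(p.tm_wallace - cfg.tm_mid), p.footprint[0], len(p)))
    return candidates


def design_species_reverse(
    aln: SpeciesAlignment,
    target: str,
    sites: Sequence[DiagnosticSite],
    cfg: DesignConfig,
) -> list[Primer]:
    """3'-anchored reverse-primer candidates for one target species.

    A reverse primer is the reverse complement of a plus-strand footprint,
    so its 3'-terminal base pairs the *lowest* footprint column.  For each
    diagnostic site ``s`` and admissible length ``L`` the candidate footprint
    is therefore ``[s, s+L-1]``, built from the target consensus: the 3' base
    pairs the target allele at ``s`` and mismatches every non-target there.
    Ranked by (diagnostic-site count desc, Tm closeness, leftmost footprint).
    """
    consensus = species_consensus(aln, target)
    site_columns = {s.column for s in sites}
    candidates: list[Primer] = []
    for site in sorted(sites, key=lambda s: s.column):
        for length in range(cfg.primer_len_min, cfg.primer_len_max + 1):
            end = site.column + length - 1
            if end > aln.length:
                continue
            footprint_seq = consensus[site.column - 1 : end]
            if GAP in footprint_seq or set(footprint_seq) - set("ACGT"):
                continue  # footprint crosses a gap or an unresolved column
            seq = revcomp(footprint_seq)
            if not _passes_qc(seq, cfg):
                continue
            offsets = tuple(
                sorted(c - site.column for c in site_columns if site.column <= c <= end)
            )
            if len(offsets) < cfg.min_diag_in_footprint:
                continue
            candidates.append(
                Primer(
                    name=f"R_{target}_{site.column}_{end}",
                    sequence=seq,
                    orientation="reverse",
                    target_species=target,
                    footprint=(site.column, end),
                    tm_wallace=tm_wallace(seq),
                    tm_nn=tm_nearest_neighbor(seq) if len(seq) >= 8 else float("nan"),
                    gc=gc_content(seq),
                    diagnostic_offsets=offsets,
                )
            )
    candidates.sort(
        key=lambda p: (
            -len(p.diagnostic_offsets),
            abs(p.tm_wallace - cfg.tm_mid),
            p.footprint[0],
        )
    )
    return candidates


def dimer_score(p: Primer | str, q: Primer | str) -> int:
    """Max run of contiguous Watson-Crick pairs over all antiparallel
    ungapped annealing registers of the two sequences (symmetric)."""
    a = p.sequence if isinstance(p, Primer) else p
    b = q.sequence if isinstance(q, Primer) else q
    b_rev = b[::-1]
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    best = 0
    for shift in range(-(len(b_rev) - 1), len(a)):
        run = 0
        for i in range(len(a)):
            j = i - shift
            if 0 <= j < len(b_rev):
                if comp.get(a[i]) == b_rev[j]:
                    run += 1
                    best = max(best, run)
                else:
                    run = 0
    return best


def _physical_span(consensus: str, start: int, end: int) -> int:
    """Template length of alignment interval [start, end] on gap-stripped
    target coordinates."""
    return sum(1 for ch in consensus[start - 1 : end] if ch != GAP)


def assemble_panel(
    forwards: Sequence[Primer],
    reverses: Mapping[str, Sequence[Primer]],
    cfg: DesignConfig,
    aln: SpeciesAlignment | None = None,
) -> PrimerPanel:
    """Greedy deterministic panel assembly in candidate rank order.

    Species are processed in sorted-name order; for each, the first reverse
    candidate compatible with everything chosen so far is taken.  Raises
    :class:`PanelInfeasibleError` naming the binding constraint otherwise.
    """
    if not forwards:
        raise PanelInfeasibleError("no_forward_candidates", "empty forward candidate list")
    for sp, cands in reverses.items():
        if not cands:
            raise PanelInfeasibleError(
                "no_reverse_candidates", f"no reverse candidates for species {sp!r}"
            )
    consensus_by_species = (
        {sp: species_consensus(aln, sp) for sp in reverses} if aln is not None else {}
    )
    last_block = ("no_feasible_combination", "exhausted all forward candidates")

    for fwd in forwards:
        chosen: dict[str, Primer] = {}
        sizes: dict[str, int] = {}
        ok = True
        for sp in sorted(reverses):
            picked = None
            for rev in reverses[sp]:
                if rev.footprint[0] <= fwd.footprint[1]:
                    last_block = ("orientation", f"{rev.name} not 3' of forward")
                    continue
                if sp in consensus_by_species:
                    size = _physical_span(
                        consensus_by_species[sp], fwd.footprint[0], rev.footprint[1]
                    )
                else:
                    size = rev.footprint[1] - fwd.footprint[0] + 1
                if not cfg.min_amplicon <= size <= cfg.max_amplicon:
                    last_block = ("amplicon_size", f"{rev.name} gives {size} bp")
                    continue
                if any(abs(size - s) < cfg.min_separation for s in sizes.values()):
                    last_block = ("min_separation", f"{rev.name} size {size} bp too close")
                    continue
                partners = [fwd] + list(chosen.values()) + [rev]
                if max(dimer_score(x, rev) for x in partners) > cfg.dimer_threshold:
                    last_block = ("dimer", f"{rev.name} exceeds dimer threshold")
                    continue
                tms = [p.tm_wallace for p in partners]
                if max(tms) - min(tms) > cfg.max_tm_spread:
                    last_block = ("tm_spread", f"{rev.name} exceeds Tm spread")
                    continue
                picked = (rev, size)
                break
            if picked is None:
                ok = False
                break
            chosen[sp] = picked[0]
            sizes[sp] = picked[1]
        if ok:
            return PrimerPanel(
                forward=fwd,
                reverses=dict(chosen),
                expected_sizes=dict(sizes),
                min_separation=cfg.min_separation,
            )
    raise PanelInfeasibleError(*last_block)


# ---------------------------------------------------------------------------
# Panel serialization
# ---------------------------------------------------------------------------

def _primer_to_dict(p: Primer) -> dict:
    d = asdict(p)
    d["footprint"] = list(p.footprint) if p.footprint else None
    d["diagnostic_offsets"] = list(p.diagnostic_offsets)
    return d


def _primer_from_dict(d: Mapping) -> Primer:
    return Primer(
        name=d["name"],
        sequence=d["sequence"],
        orientation=d["orientation"],
        target_species=d.get("target_species", UNIVERSAL),
        footprint=tuple(d["footprint"]) if d.get("footprint") else None,
        tm_wallace=d.get("tm_wallace", 0.0),
        tm_nn=d.get("tm_nn", 0.0),
        gc=d.get("gc", 0.0),
        diagnostic_offsets=tuple(d.get("diagnostic_offsets", ())),
    )


def panel_to_json(panel: PrimerPanel) -> str:
    doc = {
        "forward": _primer_to_dict(panel.forward),
        "reverses": {sp: _primer_to_dict(p) for sp, p in sorted(panel.reverses.items())},
        "expected_sizes": {sp: panel.expected_sizes[sp] for sp in sorted(panel.expected_sizes)},
        "min_separation": panel.min_separation,
    }
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def panel_from_json(text: str) -> PrimerPanel:
    doc = json.loads(text)
    return PrimerPanel(
        forward=_primer_from_dict(doc["forward"]),
        reverses={sp: _primer_from_dict(d) for sp, d in doc["reverses"].items()},
        expected_sizes={sp: int(v) for sp, v in doc["expected_sizes"].items()},
        min_separation=int(doc["min_separation"]),
    )


TSV_HEADER = "Primer\tSpecificity\tPrimer Sequence (5'-3')\tSize (bp)"


def panel_to_tsv(panel: PrimerPanel) -> str:
    lines = [TSV_HEADER, f"{panel.forward.name}\tAll\t{panel.forward.sequence}\t"]
    for sp in sorted(panel.reverses):
        p = panel.reverses[sp]
        lines.append(f"{p.name}\t{sp}\t{p.sequence}\t{panel.expected_sizes[sp]}")
    return "\n".join(lines) + "\n"


def panel_from_tsv(text: str, min_separation: int | None = None) -> PrimerPanel:
    """Load a panel from a 4-column TSV (Primer, Specificity, Sequence, Size).

    The forward primer is the row whose specificity is ``All`` (case
    insensitive) or ``universal``; footprints are unknown for external panels.
    """
    forward: Primer | None = None
    reverses: dict[str, Primer] = {}
    sizes: dict[str, int] = {}
    for line in text.splitlines():
        if not line.strip() or line.lower().startswith("primer\t"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed panel row: {line!r}")
        name, spec, seq = parts[0].strip(), parts[1].strip(), parts[2].strip().upper()
        size = parts[3].strip() if len(parts) > 3 else ""
        if spec.lower() in ("all", UNIVERSAL):
            forward = Primer(
                name=name, sequence=seq, orientation="forward",
                target_species=UNIVERSAL,
                tm_wallace=tm_wallace(seq), gc=gc_content(seq),
            )
        else:
            reverses[spec] = Primer(
                name=name, sequence=seq, orientation="reverse", target_species=spec,
                tm_wallace=tm_wallace(seq), gc=gc_content(seq),
            )
            sizes[spec] = int(size) if size else 0
    if forward is None:
        raise ValueError("panel TSV lacks a universal forward primer row")
    if not reverses:
        raise ValueError("panel TSV lacks reverse primer rows")
    seps = sorted(sizes.values())
    derived_sep = min(
        (b - a for a, b in zip(seps, seps[1:])), default=1
    )
    return PrimerPanel(
        forward=forward,
        reverses=reverses,
        expected_sizes=sizes,
        min_separation=min_separation if min_separation is not None else max(1, derived_sep),
    )


def load_panel(path: str | Path) -> PrimerPanel:
    """Load a panel from a ``.json`` or ``.tsv`` file by extension."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return panel_from_json(text)
    return panel_from_tsv(text)
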