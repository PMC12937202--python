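"""In-silico multiplex PCR with 3'-mismatch extension blocking.

Binding sites are found by exhaustive scanning of both template strands
(templates are barcode-length, so correctness and auditability beat speed).
A primer placement is *extendable* only if its 3'-terminal base matches and
at most ``max_mismatch_in_window`` mismatches fall inside the 3' window —
the allele-specific mechanism that keeps species-specific reverse primers
from amplifying non-target templates.

IUPAC ambiguity in templates counts as a match when compatible, which is
conservative toward reporting risky amplification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .primer_design import Primer, PrimerPanel
from .seqio import GAP, SequenceRecord, iupac_compatible, revcomp

__all__ = [
    "BindingSite",
    "Amplicon",
    "PcrConfig",
    "find_binding_sites",
    "amplify",
    "multiplex_pcr",
    "specificity_matrix",
]


@dataclass(frozen=True)
class BindingSite:
    """One annealed placement of a primer on a template strand.

    ``start``/``end`` are 1-based inclusive plus-strand template coordinates
    of the footprint.  On the plus strand the primer's 3' terminus is at
    ``end``; on the minus strand it is at ``start``.
    """

    template_id: str
    strand: str  # "plus" | "minus"
    start: int
    end: int
    mismatches: int
    mismatch_positions_from_3prime: tuple[int, ...]
    extendable: bool


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product on the plus strand of one template."""

    template_id: str
    species: str
    forward_site: BindingSite
    reverse_site: BindingSite
    forward_name: str
    reverse_name: str

    @property
    def length(self) -> int:
        return self.reverse_site.end - self.forward_site.start + 1

    @property
    def start(self) -> int:
        return self.forward_site.start

    @property
    def end(self) -> int:
        return self.reverse_site.end


@dataclass(frozen=True)
class PcrConfig:
    max_mismatch_total: int = 3
    three_prime_window: int = 5
    max_mismatch_in_window: int = 1
    block_on_terminal_mismatch: bool = True
    min_amplicon: int = 50
    max_amplicon: int = 2000

    @classmethod
    def from_dict(cls, d: Mapping) -> "PcrConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


def _scan_strand(
    primer_seq: str,
    template_seq: str,
    template_id: str,
    strand: str,
    cfg: PcrConfig,
) -> list[BindingSite]:
    """Naive scan of one strand; ``primer_seq`` is pre-oriented so that
    position i pairs plus-strand position (offset + i)."""
    n, m = len(template_seq), len(primer_seq)
    sites: list[BindingSite] = []
    for offset in range(n - m + 1):
        mism: list[int] = []
        for i in range(m):
            if not iupac_compatible(primer_seq[i], template_seq[offset + i]):
                mism.append(i)
                if len(mism) > cfg.max_mismatch_total:
                    break
        if len(mism) > cfg.max_mismatch_total:
            continue
        start, end = offset + 1, offset + m
        if strand == "plus":
            offsets3 = tuple(sorted(m - 1 - i for i in mism))
        else:
            offsets3 = tuple(sorted(mism))
        extendable = True
        if cfg.block_on_terminal_mismatch and 0 in offsets3:
            extendable = False
        if sum(1 for o in offsets3 if o < cfg.three_prime_window) > cfg.max_mismatch_in_window:
            extendable = False
        sites.append(
            BindingSite(
                template_id=template_id,
                strand=strand,
                start=start,
                end=end,
                mismatches=len(mism),
                mismatch_positions_from_3prime=offsets3,
                extendable=extendable,
            )
        )
    return sites


def find_binding_sites(
    template: SequenceRecord, primer: Primer | str, cfg: PcrConfig | None = None
) -> list[BindingSite]:
    """Every placement of the primer on either template strand with at most
    ``max_mismatch_total`` IUPAC-incompatible positions, sorted by coordinate."""
    cfg = cfg or PcrConfig()
    seq = primer.sequence if isinstance(primer, Primer) else primer
    if GAP in template.residues:
        raise ValueError(f"template {template.id!r} contains gaps; ungap it first")
    if len(seq) > len(template.residues):
        return []
    plus = _scan_strand(seq, template.residues, template.id, "plus", cfg)
    # Minus strand: the primer anneals where the plus strand reads revcomp(primer).
    minus = _scan_strand(revcomp(seq), template.residues, template.id, "minus", cfg)
    return sorted(plus + minus, key=lambda s: (s.start, s.strand))


def amplify(
    template: SequenceRecord,
    forward: Primer,
    reverse: Primer,
    cfg: PcrConfig | None = None,
) -> list[Amplicon]:
    """All products from extendable (plus-strand forward, minus-strand
    reverse) site pairs with the forward upstream and length within range."""
    cfg = cfg or PcrConfig()
    fwd_sites = [
        s for s in find_binding_sites(template, forward, cfg)
        if s.strand == "plus" and s.extendable
    ]
    rev_sites = [
        s for s in find_binding_sites(template, reverse, cfg)
        if s.strand == "minus" and s.extendable
    ]
    out: list[Amplicon] = []
    for f in fwd_sites:
        for r in rev_sites:
            if f.start >= r.start or f.end >= r.end:
                continue
            length = r.end - f.start + 1
            if cfg.min_amplicon <= length <= cfg.max_amplicon:
                out.append(
                    Amplicon(
                        template_id=template.id,
                        species=reverse.target_species,
                        forward_site=f,
                        reverse_site=r,
                        forward_name=forward.name,
                        reverse_name=reverse.name,
                    )
                )
    out.sort(key=lambda a: (a.start, a.end))
    return out


def multiplex_pcr(
    templates: Sequence[SequenceRecord],
    panel: PrimerPanel,
    cfg: PcrConfig | None = None,
) -> dict[str, list[Amplicon]]:
    """Products of the full panel on each template, keyed by template id."""
    cfg = cfg or PcrConfig()
    result: dict[str, list[Amplicon]] = {}
    for template in templates:
        amps: list[Amplicon] = []
        for sp in sorted(panel.reverses):
            amps.extend(amplify(template, panel.forward, panel.reverses[sp], cfg))
        amps.sort(key=lambda a: (a.start, a.end, a.species))
        result[template.id] = amps
    return result


def specificity_matrix(
    panel: PrimerPanel,
    templates: Sequence[SequenceRecord],
    cfg: PcrConfig | None = None,
) -> pd.DataFrame:
    """Species x species amplicon counts.

    Row i = template species, column j = reverse-primer species; entry (i, j)
    counts amplicons from the universal forward + reverse primer j on the
    species-i templates.  A valid panel is diagonal.
    """
    cfg = cfg or PcrConfig()
    for t in templates:
        if not t.species:
            raise ValueError(f"template {t.id!r} lacks a species label")
    template_species = sorted({t.species for t in templates})
    primer_species = sorted(panel.reverses)
    mat = pd.DataFrame(0, index=template_species, columns=primer_species, dtype=int)
    for t in templates:
        for sp in primer_species:
            amps = amplify(t, panel.forward, panel.reverses[sp], cfg)
            mat.loc[t.species, sp] += len(amps)
    mat.index.name = "template_species"
    mat.columns.name = "primer_species"
    return mat


def is_diagonal(matrix: pd.DataFrame) -> bool:
    """True iff every diagonal entry is positive and every off-diagonal zero
    (species appearing only as templates must produce nothing)."""
    for ts in matrix.index:
        for ps in matrix.columns:
            v = matrix.loc[ts, ps]
            if ts == ps:
                if v <= 0:
                    return False
            elif v != 0:
                return False
    return True
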