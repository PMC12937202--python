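"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles against the
definitions, without importing the implementation's column profiles, scan
loops, or thermodynamic code, so that oracle and implementation stay two
separate routes to the same answer.
"""

from __future__ import annotations

from collections import Counter

# Base sets re-derived by hand from the IUPAC code definitions.
AMBIG = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def brute_force_diagnostic_sites(records, target):
    """(column, allele) pairs diagnostic for ``target``.

    ``records`` is a list of (species, residues) tuples.  Re-derives the
    definition per column with raw string operations.
    """
    length = len(records[0][1])
    out = []
    for col in range(1, length + 1):
        chars = [(sp, seq[col - 1]) for sp, seq in records]
        if any(c == "-" for _, c in chars):
            continue
        target_chars = {c for sp, c in chars if sp == target}
        if len(target_chars) != 1:
            continue
        allele = target_chars.pop()
        if allele not in "ACGT":
            continue
        clash = False
        for sp, c in chars:
            if sp != target and allele in AMBIG[c]:
                clash = True
                break
        if not clash:
            out.append((col, allele))
    return out


def brute_force_conserved_columns(records):
    """Set of 1-based columns carrying one identical unambiguous base."""
    length = len(records[0][1])
    cols = set()
    for col in range(1, length + 1):
        chars = {seq[col - 1] for _, seq in records}
        if len(chars) == 1 and chars <= set("ACGT"):
            cols.add(col)
    return cols


def naive_binding_scan(primer, template, max_mismatch, window, window_max, block_terminal):
    """Position-by-position scorer for primer placements on both strands.

    Returns tuples (strand, start, end, mismatch_offsets_from_3prime,
    extendable) with 1-based inclusive plus-strand coordinates.  The minus
    strand is handled by explicitly reverse-complementing the *template* and
    mapping coordinates back, which is a different route from the
    implementation (it reverse-complements the primer).
    """
    n, m = len(template), len(primer)
    results = []

    def compat(p, t):
        return bool(set(AMBIG[p]) & set(AMBIG[t]))

    # plus strand: primer as written, 3' end at the right
    for off in range(n - m + 1):
        mm = [m - 1 - i for i in range(m) if not compat(primer[i], template[off + i])]
        if len(mm) <= max_mismatch:
            ext = not (block_terminal and 0 in mm)
            if sum(1 for o in mm if o < window) > window_max:
                ext = False
            results.append(("plus", off + 1, off + m, tuple(sorted(mm)), ext))

    # minus strand via reverse-complemented template
    rc = "".join(COMP.get(c, {"R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M",
                              "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
                              "N": "N"}.get(c, "?")) for c in reversed(template))
    for off in range(n - m + 1):
        mm = [m - 1 - i for i in range(m) if not compat(primer[i], rc[off + i])]
        if len(mm) <= max_mismatch:
            ext = not (block_terminal and 0 in mm)
            if sum(1 for o in mm if o < window) > window_max:
                ext = False
            # position i of rc corresponds to plus-strand position n - i
            start, end = n - (off + m) + 1, n - off
            results.append(("minus", start, end, tuple(sorted(mm)), ext))
    return sorted(results, key=lambda r: (r[1], r[0]))


def wallace_recount(seq):
    """Wallace rule recomputed via a Counter rather than str.count."""
    c = Counter(seq)
    return 2 * (c["A"] + c["T"]) + 4 * (c["G"] + c["C"])


def nn_tm_reference(seq, na_mM, oligo_nM):
    """Biopython's NN melting temperature under the same documented
    parameter set (unified 2004 table, entropic salt correction)."""
    from Bio.SeqUtils import MeltingTemp as mt

    return mt.Tm_NN(
        seq, nn_table=mt.DNA_NN4, Na=na_mM, dnac1=oligo_nM, dnac2=0, saltcorr=5
    )
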