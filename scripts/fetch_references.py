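#!/usr/bin/env python
"""Fetch the five reference COI GenBank records into data/reference_coi.fasta.

Requires network access to NCBI.  The resulting file enables the
accession-based acceptance tests (criteria 1 and 2) and the t1-t5 entries of
scripts/acceptance.py; everything else in the test suite is self-contained.
"""

from __future__ import annotations

import sys
import time
import urllib.parse
import urllib.request
from pathlib import Path

ACCESSIONS = {
    "MZ831962": "Onchidium stuxbergi",
    "NC_068813": "Peronia verruculata",
    "OP714175": "Onchidium reevesii",
    "MZ832009": "Platevindex martensi",
    "MH054945": "Paromoionchis tumidus",
}

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"


def fetch(accession: str) -> str:
    params = urllib.parse.urlencode(
        {"db": "nucleotide", "id": accession, "rettype": "fasta", "retmode": "text"}
    )
    with urllib.request.urlopen(f"{EFETCH}?{params}", timeout=60) as resp:
        return resp.read().decode()


def main() -> int:
    out = Path(__file__).resolve().parent.parent / "data" / "reference_coi.fasta"
    out.parent.mkdir(exist_ok=True)
    chunks = []
    for acc, species in ACCESSIONS.items():
        sys.stderr.write(f"fetching {acc} ({species})...\n")
        text = fetch(acc).strip()
        if not text.startswith(">"):
            sys.stderr.write(f"unexpected response for {acc}\n")
            return 1
        header, _, body = text.partition("\n")
        label = species.replace(" ", "_")
        chunks.append(f">{acc} species={label}\n{body}\n")
        time.sleep(0.4)  # NCBI rate limit courtesy
    out.write_text("".join(chunks))
    sys.stderr.write(f"wrote {out}\n")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
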