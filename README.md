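# snap-pcr

Toolkit for building **multiplex species-specific PCR identification panels**
from a barcode-gene alignment (e.g. COI). Given a species-labelled multiple
sequence alignment it:

1. **scans** for diagnostic SNPs — columns where one species is fixed for a
   base no other species carries — and for pan-species conserved windows
   (`snap_pcr.diagnostics`);
2. **designs** one universal forward primer (inside a conserved window) and
   per-species reverse primers whose 3′-terminal base sits on a diagnostic
   SNP, then assembles a panel whose amplicon sizes form a resolvable ladder
   (`snap_pcr.primer_design`);
3. **validates** the panel by in-silico multiplex PCR with 3′-mismatch
   extension blocking (`snap_pcr.insilico_pcr`) and renders a virtual
   agarose gel (`snap_pcr.virtual_gel`).

A synthetic-data generator (`snap_pcr.synthetic_data`) emits species
alignments with planted conserved windows, planted diagnostic SNPs and
controlled intraspecific noise, together with machine-readable ground truth,
so the whole pipeline is testable without downloads.

An example six-primer panel for five onchidiid slug species (universal
forward + five species-specific reverse primers, amplicons
162/227/275/307/527 bp) is bundled as
`snap_pcr/data/onchidiid_coi_panel.tsv`.

## CLI

```bash
snap config --show-defaults                       # all tunable knobs
snap simulate --spec spec.yaml --out-prefix sim   # synthetic alignment + truth
snap scan     --alignment aln.fasta --species-map sp.tsv \
              --sites-out sites.tsv --windows-out windows.bed
snap design   --alignment aln.fasta --species-map sp.tsv --out-dir out/
snap ispcr    --panel out/panel.json --templates templates.fasta --out-dir pcr/
snap validate --panel out/panel.json --templates templates.fasta \
              --species-map sp.tsv --out-dir val/   # exit 0 iff specificity diagonal
snap gel      --amplicons pcr/amplicons.tsv --out gel.txt [--png gel.png]
```

Species labels come from a two-column TSV (`record_id<TAB>species`) or from
`species=` tokens in FASTA headers. Alignment coordinates are 1-based
inclusive everywhere; the BED-like window file is 0-based half-open. Every
run writes a `manifest.json` with SHA-256 digests of its inputs; identical
inputs and config give byte-identical outputs.

## Notes on models

- Wallace Tm: 2(A+T) + 4(G+C). Nearest-neighbor Tm: unified SantaLucia-2004
  parameter set, entropic salt correction 0.368·(N−1)·ln[Na⁺], duplex term
  at the supplied oligo concentration (cross-checked against Biopython).
- Extension blocking: a 3′-terminal mismatch always blocks; more than one
  mismatch within the 5-nt 3′ window also blocks (both configurable).
- Virtual gel: log-linear mobility `d = a − b·log10(bp)`; the default
  constants approximate a 2.75 % gel and carry no quantitative claims.
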