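"""snap-pcr: diagnostic-SNP discovery and multiplex species-specific PCR
panel design from barcode-gene alignments, with in-silico PCR and
virtual-gel validation."""

__version__ = "0.1.0"

from importlib import resources as _resources


def example_panel_path():
    """Path to the bundled onchidiid COI example primer panel (TSV)."""
    return _resources.files("snap_pcr").joinpath("data/onchidiid_coi_panel.tsv")
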