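Primer	Specificity	Primer Sequence (5'-3')	Size (bp)
COforward	All	AATGTTATTGTGACTGCTCATGC
COOst162r	Onchidium stuxbergi	AAGAAGGAGGTAGCAACCAG	162
COPve227r	Peronia verruculata	AGGATAAACTGTTCATCCTGTC	227
COOre275r	Onchidium reevesii	CACCAAGTCTACAGACGCTCCC	275
COPma307r	Platevindex martensi	GATGATATACCAGCCAAATGAAG	307
COPtu527r	Paromoionchis tumidus	TAAAATAGGATCACCACCTCCC	527
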