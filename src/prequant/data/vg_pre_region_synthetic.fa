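>vg_pre_region_synthetic synthetic surrogate template: the 106 bp region plus downstream primer-annealing context
AAGAGGTTGAACCCCTTGAGGAGAGCAGGAAACCGGTTTATTTCCACAACTCCGTGTGTC
TGTGCGTGGTGTGAGTGTGTGCGTTTATGCCTGTGTGCGAATCGCTAGTTTGTGTGAGAG
TGAGCATCACGGATTTTCGACCACTTCTATATGCTC
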