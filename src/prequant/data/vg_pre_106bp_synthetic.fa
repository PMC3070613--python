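>vg_pre_106bp_synthetic synthetic surrogate for the first 106 bp of the 1.6 kb vg PRE; one GAGAG site and four GTGT repeat blocks; primer-anchored
AAGAGGTTGAACCCCTTGAGGAGAGCAGGAAACCGGTTTATTTCCACAACTCCGTGTGTC
TGTGCGTGGTGTGAGTGTGTGCGTTTATGCCTGTGTGCGAATCGCT
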