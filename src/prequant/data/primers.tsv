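name	direction	sequence	enzyme
vg1.6kb	forward	TAAAGCGGCCGCAAGTCTCCGCCCAATAAT	NotI
vgD100	forward	TAAAGCGGCCGCAGTTTGTGTGAGAGTGAGC	NotI
vgD300	forward	TAAAGCGGCCGCCGTAATTAAAACCGAAGG	NotI
vg_all	reverse	GCGCTTTCTAGAGAGCATATAGAAGTGGTCGAA	XbaI
Fab7	forward	TAAAGCGGCCGCGGAATTGTGTGGACGATG	NotI
Fab7	reverse	GGCGCTTACTAGTGCACAGAGAGTGCAGAAAG	SpeI
vgDGAGA	forward	AAGAGGTTGAACCCCTTGAGGAAACCGGTTTATTTC	-
vgDGAGA	reverse	GAAATAAACCGGTTTCCTCAAGGGGTTCAACCTCTT	-
vgD1stGT	forward	CAGGAAACCGGTTTATTTCCACAACTCTGTGCGTG	-
vgD1stGT	reverse	CACGCACAGAGTTGTGGAAATAAACCGGTTTCCTG	-
vgD1st2ndGT	forward	GGTTTATTTCCACAACTCCGTGTGTGCGTTTATGCC	-
vgD1st2ndGT	reverse	GGCATAAACGCACACACGGAGTTGTGGAAATAAACC	-
vgD1st3rdGT	forward	GTTTATTTCCACAACTCCCGTTTATGCCTGTGTGCG	-
vgD1st3rdGT	reverse	CGCACACAGGCATAAACGGGAGTTGTGGAAATAAAC	-
vgD1st4thGT	forward	CAACTCCCGTTTATGCCCGCTAGTTTGTGTGAGA	-
vgD1st4thGT	reverse	TCTCACACAAACTAGCGGGCATAAACGGGAGTTG	-
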