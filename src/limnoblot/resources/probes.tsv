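name	sequence	tm
Lim1+	CTGTGTCAAAGAGTTATTCACATT	55.9
Lim2+	AAACTTTGTTCGCATTACGGC	55.9
Lim3+	AAATAGCTTTGATCTTGAAAGAGGT	56.4
Lim4AusCurv+Lim3+	ATTGATTGATTAACTAGGCTGTTC	55.9
Lim4AusCurv	AGATATCAGAGTTRCTAGCGG	56.9
Lim5+	CGGCTGAGGCGTAAGC	56.9
Lim6+A	ACGACTTGTGCGCATGCT	56.0
Lim6+B	CGCGTAAATCGAATAAATCCAATA	55.9
Lim7+A	CGCAAGCCTCGAGTCATT	56.0
Lim7+B	CGCAAGCCCAAGTCATTG	56.0
Lim7+C	CTTATCAAAGGTTTTGATCTCATTC	56.4
Lim7+D	ACTTATCAAATGTTTTGATCTCATTCAA	56.3
Lim8Parv+	TATCGAGTGTTAATRGTGTCTGA	56.2
Lim9Plankt+	GGGCCTTGCAGTGGC	56.0
Lim10+	TTGAGCGGATCCTGCAAG	56.0
Lim11+	AAGAGATTGCGAGGCTGTTTT	55.9
Lim12+A	GTTCCCGTAAGGGACTTTAT	55.3
Lim13+	GGGTCTTGCAAGGGCC	56.9
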