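assay	target	fwd_name	fwd_seq	rev_name	rev_seq	printed_bp	mrna_fold	abc
FBXL12	FBXL12	FBXL12-143F	ACCTGACGCTCTACACGATGC	FBXL12-251R	GAGCCAGAGAACAGGTAGCCA	108
A-locus-long	HLA-A	HLA A-minus2F	GGATGGCCGTCATGGCGCC	HLA A-1063R	CCTGGGCACTGTCACTGCTT	1065
B-locus-long	HLA-B	HLA B-minus40F	CACGCACCCACCCGGACTCA	HLA-B-1091R	TTTCAAGCTGTGAGAGACACATCA	1143
C-locus-long	HLA-C	HLA-Cw-minus49F	TAAAGTCCCCAGTCACCCACC	HLA Cw-1073R	TCAGAGCCCTGGGCACTGTT	1122
A020101	A*02:01:01	HLA-A020101-272F	TGAAGGCCCACTCACAGACTC	HLA-A020101-383R	CCCACGTCGCAGCCATACATT	111	8.9	204370
A0301	A*03:01	HLA-A0301-508F	AAGTGGGAGGCGGCCCATGA	HLA-A0301-636R	ATGTGTCTTGGGGGGGTCCGT	128	10.7
B0702	B*07:02	HLA-B0702-522F	CCGTGAGGCGGAGCAGCG	HLA-B0702-621R	GTCAGCGCGCTCCAGCTTG	99	30.1	12076
B2702	B*27:02	HLA-B2702-232F	GGGACCGGGAGACACAGATC	HLA-B2702-337R	CGCTCTGGTTGTAGTAGCGGA	105	41.8	5174
C020202	C*02:02:02	HLA-Cw020202-101F	CCGCTGTGTCCCGGCCCA	HLA-Cw020202-218F	GCCCGCGGCTCCCCTCTT	117	18.6
C0702	C*07:02	HLA-Cw0702-972F	TGGAGCTGTGGTCACCGCTA			95	5.4
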