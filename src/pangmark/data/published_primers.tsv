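name	target_label	forward	reverse	expected_size_bp	target_gene	accession
Bulgaricus	bulgaricus	TACCGCTGTTCTGTCTCAAGG	TATGCCTCCGTGAGCGATCT	102	YcaO-like family protein	ABJ57813.1
Lactis	lactis	TTGTGCAAGAGCCAGCTGAA	GCCGCCATTACTGAAGTGGA	113	Ser/Thr protein kinase	EGD27206.1
Delbrueckii	delbrueckii	CATGGAACTTCTGCGAAGGT	TAGATCCGGAGCTGTTCCAC	110	Choline kinase	KNZ37552.1
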