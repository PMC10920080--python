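cohort	age_class	gene	altered	n
LOPC-ICGC	LOPC	KRAS	617	659
LOPC-ICGC	LOPC	CDKN2A	155	659
LOPC-ICGC	LOPC	TP53	483	659
LOPC-ICGC	LOPC	SMAD4	201	659
EOPC-ICGC	EOPC	KRAS	57	63
EOPC-ICGC	EOPC	CDKN2A	11	63
EOPC-ICGC	EOPC	TP53	46	63
EOPC-ICGC	EOPC	SMAD4	16	63
EOPC-ours	EOPC	KRAS	29	33
EOPC-ours	EOPC	CDKN2A	17	33
EOPC-ours	EOPC	TP53	27	33
EOPC-ours	EOPC	SMAD4	11	33
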