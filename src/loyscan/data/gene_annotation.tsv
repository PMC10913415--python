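id	symbol	chromosome	is_msy	is_par	is_mito
RPS4Y1	RPS4Y1	chrY	1	0	0
DDX3Y	DDX3Y	chrY	1	0	0
EIF1AY	EIF1AY	chrY	1	0	0
UTY	UTY	chrY	1	0	0
KDM5D	KDM5D	chrY	1	0	0
USP9Y	USP9Y	chrY	1	0	0
ZFY	ZFY	chrY	1	0	0
NLGN4Y	NLGN4Y	chrY	1	0	0
TMSB4Y	TMSB4Y	chrY	1	0	0
CD99	CD99	chrX;chrY	0	1	0
MT-CO1	MT-CO1	chrM	0	0	1
MT-ND1	MT-ND1	chrM	0	0	1
MT-CYB	MT-CYB	chrM	0	0	1
MT-ATP6	MT-ATP6	chrM	0	0	1
MT-ND4	MT-ND4	chrM	0	0	1
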