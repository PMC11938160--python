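code	template	sialyl_category	sialic_type
N	N	none	none
NH	N(H)	none	none
NHH	N(H(H))	none	none
NHNH	N(H(N(H)))	none	none
NHF	N(F)(H)	none	none
NHS	N(H(S))	terminal-sialyl-LacNAc	Neu5Ac
NHG	N(H(G))	terminal-sialyl-LacNAc	Neu5Gc
NHFS	N(F)(H(S))	sialyl-Lewis	Neu5Ac
NHFG	N(F)(H(G))	sialyl-Lewis	Neu5Gc
N(S)H	N(H)(S)	antenna-sialyl-LacNAc	Neu5Ac
N(G)H	N(G)(H)	antenna-sialyl-LacNAc	Neu5Gc
N(S)HS	N(H(S))(S)	bi-sialyl-LacNAc	Neu5Ac
N(G)HG	N(G)(H(G))	bi-sialyl-LacNAc	Neu5Gc
N2	N(N)	none	none
N2S	N(N(S))	none	Neu5Ac
N2G	N(N(G))	none	Neu5Gc
N2F	N(F)(N)	none	none
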