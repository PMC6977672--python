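symbol	immune_class	aliases
AttA	AMP	AttacinA
AttB	AMP	AttacinB
AttC	AMP	AttacinC
AttD	AMP	AttacinD
CecA1	AMP	CecA
CecA2	AMP
CecB	AMP
CecC	AMP
DptA	AMP	Dpt
DptB	AMP
Drs	AMP	Drosomycin
Def	AMP	Defensin
Dro	AMP	Drosocin
Mtk	AMP	Metchnikowin
LysS	lysozyme
LysB	lysozyme
LysD	lysozyme
LysE	lysozyme
LysP	lysozyme
PGRP-LC	PGRP
PGRP-SA	PGRP
PGRP-SD	PGRP
PGRP-LE	PGRP
PGRP-LB	PGRP
PGRP-SB1	PGRP
GNBP1	GNBP
GNBP2	GNBP
GNBP3	GNBP
lectin-24A	lectin
lectin-28C	lectin
lectin-33A	lectin
lectin-37Da	lectin
Tl	Toll_pathway	Toll
spz	Toll_pathway	spatzle
Myd88	Toll_pathway
pll	Toll_pathway	pelle
tub	Toll_pathway	tube
cact	Toll_pathway	cactus
Dif	Toll_pathway
dl	Toll_pathway	dorsal
imd	IMD_pathway
Rel	IMD_pathway	Relish
key	IMD_pathway	kenny
Dredd	IMD_pathway
Fadd	IMD_pathway
Tak1	IMD_pathway
hop	JAKSTAT_pathway	hopscotch
dome	JAKSTAT_pathway	domeless
Stat92E	JAKSTAT_pathway
upd1	JAKSTAT_pathway	os
upd2	JAKSTAT_pathway
upd3	JAKSTAT_pathway
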