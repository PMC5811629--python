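gene	level	function	prophage
yagM	0.012	Putative protein	CP4-6
yffL	0.020	Putative protein	CPZ-55
yagL	0.023	DNA-binding protein	CP4-6
yagB	0.022	Predicted protein	CP4-6
yagG	0.026	Xyloside transporter	CP4-6
wzxB	0.029	O-antigen flippase
afuB	0.030	Predicted ferric transporter	CP4-6
intF	0.032	Putative phage integrase	CP4-6
wbbI	0.036	Putative GalF transferase
yagN	0.041	Putative protein	CP4-6
stfR	0.044	Putative membrane protein	Rac
yehB	0.047	Putative OM fimbrial usher protein
yjjJ	0.053	Toxin-like protein
yagI	0.060	XynR TF	CP4-6
wbbH	0.061	Putative O-antigen polymerase
napA	0.065	Periplasmic nitrate reductase
ygeM	0.067	Putative protein
waaI	0.069	UDP-glucose:LPS glucosyltransferase
ymfJ	0.072	Putative protein	e14
nmpC	0.075	Predicted OM porin NmpC	DLP
frvA	0.077	Fructose PTS enzyme IIA
yjiT	0.078	Conserved protein
yqiK	0.082	Putative protein
zraS	0.083	Zinc-sensing ZraSR TCS sensor kinase
ypjC	0.085	Pseudogene
yddG	0.088	Aromatic amino acid exporter
yjgL	0.094	Putative OM protein
yfjP	0.095	Predicted GTP-binding protein	CP4-57
waaP	0.095	LP core heptose kinase
yciC	0.098	Putative IM protein
chiA	0.100	Endochitinase
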