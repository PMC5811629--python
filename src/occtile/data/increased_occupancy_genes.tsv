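gene	level	function	prophage
flu	82.5	Ag43 autotransporter	CP4-44
lsrA	45.4	Predicted AI-2 ABC transporter
ymfN	42.8	Putative TF	e14
ymfK	32.2	Putative repressor	e14
lsrC	31.6	Predicted AI-2 ABC transporter
nfrA	31.3	OM N4 receptor
paaE	30.6	Predicted phenylacetyl-CoA epoxidase
ydbA	29.8	Putative OM protein
ykfC	22.8	Conserved protein	CP4-6
ykfI	21.9	YfkI-YafW T-AT toxin	CP4-6
ybcH	21.7	Hypothetical protein
paaF	21.6	Putative dehydroadipyl-CoA hydratase
modC	18.4	Molybdate ABC transporter
rcsD	17.6	RcsBC TCS phosphotransfer intermediate
yjhH	16.3	Predicted lyase/synthase	KpLE2
galT	16.2	Galactose-1-phosphate uridylyltransferase
ydaY	15.8	Pseudogene	Rac
stfR	15.1	Predicted tail fiber protein	Rac
modF	15.1	Putative ABC transporter
ybhJ	14.6	Putative hydratase
ycfK	13.4	Putative protein	e14
ydaV	12.9	Putative DNA replication protein	Rac
intE	12.1	Putative integrase	e14
ymfM	12.0	Putative protein	e14
yjhG	11.6	d-Xylonate dehydrogenase	KpLE2
yfjP	11.2	Predicted GTP-binding protein	CP4-57
nfrB	11.0	NtrBC TCS sensor kinase
modA	11.0	Molybdate ABC transporter
yhcD	11.0	Putative fimbrial usher protein
ydbA	10.9	Putative protein
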