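designation	gene	ratio	sd	reciprocal	function	prophage
1	yagM	10.29	0.5	0.0972	Phage protein with unknown function	CP4-6
2	yffL	4.48	0.5	0.2233	Phage protein with unknown function	CPZ-55
3	yagN	2.44	0.6	0.4093	Phage protein with unknown function	CP4-6
4	ymfJ	1.62	0.6	0.6184	Phage protein with unknown function	e14
5	yagL	1.54	0.6	0.6405	Predicted transcription factor	CP4-6
6	intF	1.47	0.5	0.6816	Putative phage integrase	CP4-6
7	nmpC	0.99	0.9	1.0141	Putative OM protein	DPL
8	afuB	0.86	0.6	1.1638	Predicted ferric transporter	CP4-6
a	yjhH	0.95	0.7	1.0494	Putative lyase	KpLE2
b	ykfC	0.87	0.5	1.1436	Phage protein with unknown function	CP4-6
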