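gene	ratio	sd	function	prophage
ydbA	7.66	6.24	Predicted autotransporter
ybhJ	5.96	1.93	Predicted hydratase
yfjQ	4.79	1.44	OM protein assembly complex	CP4-57
paaE	4.69	2.16	1,2-Phenylacetyl-CoA epoxidase
ydaY	4.69	0.91	Phage protein	Rac
ybcH	4.54	0.21	Predicted protein
yhcD	4.53	0.46	Predicted OM usher porin protein
ymfN	3.42	0.50	DNA-binding transcription regulator	e14
basS	3.27	0.42	BasST TCS histidine kinase
yaiP	2.87	1.18	Predicted glucosyltransferase
ybhA	2.32	0.07	Pyridoxal phosphate/fructose-2P phosphatase
ycfK	2.29	1.31	Predicted protein (e14 prophage)
ymfK	2.05	0.08	DNA-binding transcription regulator	e14
nfrB	1.81	0.35	NtrBC TCS histidine kinase (N4 receptor)
flu	1.74	0.60	Ag43 autotransporter	CP4-44
isrC	1.68	0.49	IsrC sRNA (flu gene attenuation)
rcsD	1.07	0.19	RcsCDB phosphorelay phosphotransferase
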