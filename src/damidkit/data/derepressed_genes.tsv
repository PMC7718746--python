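symbol	name	ratio	fdr
Abd-B	Abdominal-B	0.43916667	1.67E-19
oc	ocelliless	0.17026667	2.66E-07
abd-A	abdominal-A	0.11543333	3.91E-07
mirr	mirror	0.1755	8.49E-06
nub	nubbin	0.08573333	1.61E-05
cad	caudal	0.17613333	4.41E-05
Inx2	Innexin 2	0.21316667	0.00027954
CAH2	Carbonic anhydrase 2	0.35613333	0.00038658
tup	tailup	0.06526667	0.0015028
Sp1	Sp1	0.04683333	0.00190136
Pdk	Pdk	0.13876667	0.00347056
Robo2	Roundabout-2	0.11006667	0.00481979
CG3777	CG3777	0.08913333	0.00529072
pim	pimples	0.5068	0.00719975
CG3262	CG3262	0.39193333	0.00728925
Psc	Posterior sex combs	0.09333333	0.00911746
CG34293	CG34293-RA	0.61326667	0.00994297
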