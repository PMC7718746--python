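genotype	normal	crumpled	cleft	single	double	lethal	n
UAS-Sce.IR-V106328/+;Ubx-GAL4,GAL80ts/+	4.0	0.0	4.0	7.4	51.7	33.0	379
UAS-Sce.IR-V106328/UAS-AbdB.IR-BL26746;Ubx-GAL4,GAL80ts/+	42.8	0.0	28.3	4.9	4.0	19.9	346
UAS-Sce.IR-V106328/UAS-AbdB.IR-BL35647;Ubx-GAL4,GAL80ts/+	47.1	9.1	3.8	6.8	10.6	22.7	397
UAS-Sce.IR-V106328/UAS-abdA.IR-BL28739;Ubx-GAL4,GAL80ts/+	36.7	12.5	7.4	7.7	11.7	23.9	376
UAS-Sce.IR-V106328/UAS-abdA.IR-BL35644;Ubx-GAL4,GAL80ts/+	37.0	9.5	4.1	7.8	17.3	24.3	243
UAS-Sce.IR-V106328/UAS-cad.IR-BL34702;Ubx-GAL4,GAL80ts/+	29.3	5.2	13.1	9.3	26.6	16.6	290
UAS-Sce.IR-V106328/UAS-cad.IR-BL57546;Ubx-GAL4,GAL80ts/+	30.8	0.5	10.0	5.0	26.9	26.9	201
UAS-Sce.IR-V106328/UAS-nub.IR-BL28338;Ubx-GAL4,GAL80ts/+	11.8	1.8	5.9	5.9	41.2	33.5	272
UAS-Sce.IR-V106328/UAS-nub.IR-BL56305;Ubx-GAL4,GAL80ts/+	28.7	7.2	15.5	7.5	17.8	23.3	387
UAS-Sce.IR-V106328/UAS-GFP;Ubx-GAL4,GAL80ts/+	4.8	0.0	17.6	9.1	42.4	26.1	165
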