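genotype	normal	weak	strong	lethal	n
+/+; Ubx-GAL4,GAL80ts/+	100.0	0.0	0.0	0.0	79
Sce.IR-V27465/+; Ubx-GAL4,GAL80ts/+	49.1	2.7	32.1	16.1	112
Sce.IR-BL31612/+; Ubx-GAL4,GAL80ts/+	61.9	16.8	18.6	2.7	113
Sce.IR-V106328/+; Ubx-GAL4,GAL80ts/+	8.9	0.0	5.1	86.1	79
Sce.IR-V106328/odd-GAL4; +/+	51.0	7.8	9.8	31.4	51
Sce.IR-V106328/+; puc-GAL4/+	88.1	2.4	2.4	7.1	42
Scm.IR-BL31614/+; Ubx-GAL4,GAL80ts/+	19.5	0.0	80.5	0.0	41
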