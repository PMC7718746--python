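assay	genotype	success_category	percent	n
overnight_eversion	control	everted	57.5	80
overnight_eversion	Sce.IR	everted	29.87	77
aj_intact_7h	control	intact	9.1	66
aj_intact_7h	Sce.IR	intact	52.0	50
bm_intact_7h	control	intact	32.8	67
bm_intact_7h	Sce.IR	intact	58.0	50
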