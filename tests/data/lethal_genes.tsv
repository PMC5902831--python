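gene_id	lethal_flag	source
GENE_LETHAL_A	1	mouse_null_embryonic
GENE_LETHAL_B	1	mouse_null_embryonic
GENE_LETHAL_C	1	mouse_null_embryonic
GENE_LETHAL_D	1	mouse_null_prenatal
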