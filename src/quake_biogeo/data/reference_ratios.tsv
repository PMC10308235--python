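# Absolute isotope ratios of reference standards used for abundance-space
# arithmetic. Results of ratio-space operations are insensitive to these
# absolute scales to first order (asserted by test).
ratio	value	provenance
VCDT_33S_32S	0.0078776	Ding et al. (2001), 32S/33S = 126.948
VCDT_34S_32S	0.0441626	Ding et al. (2001), 32S/34S = 22.6436
VSMOW_D_H	0.00015576	Hagemann et al. (1970)
VPDB_13C_12C	0.0111802	Chang & Li (1990)
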