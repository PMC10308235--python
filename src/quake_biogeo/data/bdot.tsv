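# B-dot (extended Debye-Hueckel) model constants at 25 C.
# log10 gamma_i = -A z_i^2 sqrt(I) / (1 + B a_i sqrt(I)) + Bdot * I
# A in (kg/mol)^0.5, B in (kg/mol)^0.5 / angstrom, Bdot in kg/mol.
# Provenance: Helgeson (1969) Am. J. Sci. 267:729, 25 C values.
parameter	value
A_gamma	0.5092
B_gamma	0.3283
bdot	0.0410
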