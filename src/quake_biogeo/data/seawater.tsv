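# Seawater reference composition used as the contamination endmember and as
# the sulfate sulfur-isotope reference.
# units: mM for ions, permil for isotope values.
key	value	unit	provenance
Cl	560.0	mM	open-ocean chlorinity, value used in the study context
SO4	28.0	mM	standard open-ocean sulfate (28.2 mM rounded); overridable
K	10.2	mM	standard seawater
Ca	10.3	mM	standard seawater
Mg	53.2	mM	standard seawater
Mn	0.0	mM	negligible in oxic seawater
NH4	0.0	mM	negligible in oxic seawater
dD_H2O	0.0	permil	VSMOW by definition of the marine reference
d18O_H2O	0.0	permil	VSMOW by definition of the marine reference
d34S_sulfate	21.3	permil	modern seawater sulfate (VCDT)
D33S_sulfate	0.050	permil	modern seawater sulfate (VCDT)
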