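# Aqueous species registry for ionic-strength, activity-coefficient and
# Gibbs-energy arithmetic.
# gf_kj_mol: standard-state apparent Gibbs energy of formation at 25 C, 500 bar.
#   Provenance: SUPCRT92 database values at 25 C / 1 bar (Johnson et al. 1992;
#   Shock & Helgeson 1988/1990 aqueous species) shifted to 500 bar with the
#   partial molal volume term V*(P-P0); volumes from the same compilation.
#   Retrieved and frozen 2026-09. NA where the species never enters a reaction.
# ion_size_a: B-dot (extended Debye-Hueckel) ion-size parameter in angstrom
#   (Kielland 1937 / Helgeson 1969 convention). NA for neutral species.
# composition: element counts, used for reaction element/charge balance checks.
species	charge	ion_size_a	gf_kj_mol	composition
H2O(l)	0	NA	-236.28	H:2,O:1
H2(aq)	0	NA	18.98	H:2
CO2(aq)	0	NA	-384.34	C:1,O:2
CH4(aq)	0	NA	-32.58	C:1,H:4
CH3COOH(aq)	0	NA	-393.88	C:2,H:4,O:2
CH3COO-	-1	4.5	NA	C:2,H:3,O:2
HCO3-	-1	4.5	NA	C:1,H:1,O:3
CO3-2	-2	4.5	NA	C:1,O:3
H+	1	9.0	NA	H:1
OH-	-1	3.5	NA	H:1,O:1
Na+	1	4.0	NA	Na:1
K+	1	3.0	NA	K:1
Cl-	-1	3.0	NA	Cl:1
Ca+2	2	6.0	NA	Ca:1
Mg+2	2	8.0	NA	Mg:1
Mn+2	2	6.0	NA	Mn:1
NH4+	1	2.5	NA	N:1,H:4
SO4-2	-2	4.0	NA	S:1,O:4
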