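# Acid dissociation constants (as pK) at 25 C and 500 bar.
# Provenance: 25 C / 1 bar literature values (acetic acid 4.757; carbonic
# K1 6.35, K2 10.33) shifted to 500 bar with ln(K_P/K_1) = -dV*(P-P0)/RT using
# reaction volumes dV = -11.2 (acetic), -25.4 (K1), -25.6 (K2) cm3/mol, i.e.
# the SUPCRT92-lineage pressure dependence. Frozen 2026-09.
acid	pk	provenance
acetic	4.66	CH3COOH = H+ + CH3COO-
carbonic_k1	6.13	CO2(aq) + H2O = H+ + HCO3-
carbonic_k2	10.11	HCO3- = H+ + CO3-2
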