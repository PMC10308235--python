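# Equilibrium isotope fractionation calibrations, alpha_A-B(T).
# Functional form: alpha(A-B) = 1 / (c0 + c2/T^2 + c4/T^4 + c6/T^6), T in kelvin
# (the published fits give the inverse factor alpha(B-A) as the polynomial).
# t_min_c/t_max_c delimit the temperature range over which evaluation is allowed.
pair	c0	c2	c4	c6	t_min_c	t_max_c	citation
H2-H2O	1.0473	201036.0	2.060e9	0.180e15	0.0	400.0	Horibe & Craig (1995) Geochim. Cosmochim. Acta 59:5209-5217, eq. for H2O(l)-H2
CH4-H2O	1.0997	8456.0	0.9611e9	-27.82e12	0.0	100.0	Horibe & Craig (1995) Geochim. Cosmochim. Acta 59:5209-5217, eq. for H2O(l)-CH4
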