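"""Fit kinetic D/H fractionation factors from Fe-H2O corrosion batches.

Each batch reacts granular iron with D-spiked water (dD up to ~+3000
permil) at a fixed temperature; the slope through the origin of
(1000 + dD_H2) vs (1000 + dD_H2O) is the kinetic alpha, which increases
with temperature but stays far below the equilibrium curve.
"""
from quake_biogeo import equilibrium_alpha, fit_alpha_origin
from quake_biogeo.synthetic import gen_fe_h2o_batches

batches, truth = gen_fe_h2o_batches(seed=1)
print("T (C)   alpha_kinetic   alpha_equilibrium")
for batch in batches:
    fitted = fit_alpha_origin(batch).alpha
    eq = equilibrium_alpha("H2-H2O", batch.t_celsius).alpha
    print(f"{batch.t_celsius:5.0f}   {fitted:13.3f}   {eq:17.3f}")
print("Kinetic water-rock H2 is always more D-depleted than equilibrated H2;")
print("an observed alpha of ~0.15 therefore fingerprints low-temperature,")
print("earthquake-exposed fresh rock surfaces as the H2 source.")
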