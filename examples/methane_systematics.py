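"""Methane isotope systematics: source factors, thermometry, methanotrophy.

alpha_13C(CH4-CO2) of ~0.94 indicates hydrogenotrophic methanogenesis
under H2 limitation; alpha_D(CH4-H2O) read against the CH4-H2O equilibrium
curve acts as a thermometer for aged methane; methane oxidation drags the
residual CH4 along a dD/d13C slope of ~10.
"""
from quake_biogeo import (
    alpha_from_deltas,
    equilibrium_alpha,
    methanotrophy_trajectory,
    temperature_from_alpha,
)

alpha_c = alpha_from_deltas(-64.0, -4.0).alpha
print(f"alpha_13C(CH4-CO2) from d13C_CH4 = -64, d13C_CO2 = -4 permil: "
      f"{alpha_c:.3f} (microbial, H2-limited window 0.91-0.94)")

alpha_d = alpha_from_deltas(-200.0, 0.0).alpha
t = temperature_from_alpha("CH4-H2O", alpha_d)
print(f"alpha_D(CH4-H2O) = {alpha_d:.2f} -> apparent equilibration "
      f"temperature {t:.0f} C (in situ is < 30 C: aged, equilibrated CH4)")
print(f"  (equilibrium alpha at 25 C would be "
      f"{equilibrium_alpha('CH4-H2O', 25.0).alpha:.3f})")

d13c, dd = methanotrophy_trajectory(-84.0, -200.0, shift13c=2.0)
print(f"2 permil of 13C enrichment by methanotrophy moves (-84, -200) to "
      f"({d13c:.0f}, {dd:.0f}) permil: D rises ten times faster than 13C.")
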