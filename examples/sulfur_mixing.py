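"""Multiple-sulfur-isotope systematics of sedimentary sulfide.

Chromium-reducible sulfide in the prism records microbial sulfate
reduction (large eps34, lambda33 ~ 0.514, positive D33S) overprinted by
juvenile sulfur delivered in coseismic hydrothermal fluid (d34S and D33S
both ~0). The mixing curve between the two endmembers is computed by
abundance mass balance.
"""
from quake_biogeo import (
    JUVENILE,
    MsrFractionation,
    epsilon34,
    lambda33,
    msr_forward,
    seawater_sulfate,
    sulfur_mixing_curve,
)

sulfate = seawater_sulfate()
print(f"seawater sulfate: d34S = {sulfate.delta34:+.1f}, "
      f"D33S = {sulfate.cap_delta33:+.3f} permil")

biogenic = msr_forward(sulfate, MsrFractionation(eps34=67.8, lambda33=0.514))
print(f"MSR product (eps34 = 67.8, lambda33 = 0.514): "
      f"d34S = {biogenic.delta34:+.2f}, D33S = {biogenic.cap_delta33:+.3f}")
print(f"back-calculated eps34 = "
      f"{epsilon34(biogenic.delta34, sulfate.delta34):.1f} permil, lambda33 = "
      f"{lambda33(biogenic.delta33, biogenic.delta34, sulfate.delta33, sulfate.delta34):.3f}")

print("\nmixing toward juvenile (mantle) sulfur:")
print("f_juvenile   d34S (permil)   D33S (permil)")
for f, (d34, cap) in zip(
    [0.0, 0.25, 0.5, 0.75, 1.0],
    sulfur_mixing_curve(biogenic, JUVENILE, [0.0, 0.25, 0.5, 0.75, 1.0]),
):
    print(f"{f:10.2f}   {d34:+13.2f}   {cap:+13.3f}")
print("High-TS samples plotting near (0, 0) carry the juvenile endmember;")
print("low-d34S, high-D33S samples carry the biogenic one.")
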