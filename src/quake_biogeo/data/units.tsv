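# Lithological unit depth intervals (mbsf) for Hole C0019E.
# Intervals are treated half-open [top, bottom); depths in none of the rows
# map to "gap". Units 6 and 7 are delimited jointly in the source description
# (832.9-836.8 mbsf); the joint interval is assigned to U6 and U7 is never
# returned by the default table.
unit	top_mbsf	bottom_mbsf
U1	176.5	185.2
U2	648.0	688.5
U3	688.5	820.1
U4	821.5	822.5
U5	824.0	832.9
U6	832.9	836.8
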