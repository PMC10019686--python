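# Default tomato parameter set for the dynamic leaf photosynthesis model.
# Units follow the mixed gas-exchange convention documented in params.py.

[dynamic]
ku = 179.4
kd = 830.3
c3 = 37.96

[fvcb]
Vcmax = 99.25
Rd = 1.0
Jmax = 190.68
theta = 0.41
gamma = 0.9

[temperature]
c1 = 19.02
dHa1 = 37.83
c2 = 12.3772
dHa2 = 23.72
dHa3 = 79.43
R1 = 0.008314

[physical]
R = 8.314
d = 0.0001
Pa = 101325.0
Oi = 21.0

[stomatal_target."400"]
gmin = 0.1
gmax = 0.325
alpha = 0.00033

[stomatal_target."800"]
gmin = 0.165
gmax = 0.29
alpha = 0.00017
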