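# Default single-zeta Slater 1s parameters for the shipped toy elements.
# columns: element  zeta(bohr^-1)  electrons  nuclear_charge
# H uses the exact hydrogenic exponent; He the variational single-zeta value;
# X and Y are compact "heavy" pseudo-atoms for synthetic X-H fragments.
H   1.0000  1  1
He  1.6875  2  2
X   1.8000  6  6
Y   2.4000  8  8
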