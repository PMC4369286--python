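# McGowan atomic characteristic volumes (cm^3/mol), as tabulated in the
# Abraham-model literature (Abraham & McGowan method). The molecular
# characteristic volume is V = [sum(atoms) - 6.56 * bonds] / 100 with
# bonds = atoms - 1 + rings.
element,volume_cm3_per_mol
C,16.35
H,8.71
O,12.43
N,14.39
F,10.48
Cl,20.95
Br,26.21
I,34.53
S,22.91
P,24.87
Si,26.83
B,18.32
Ge,31.02
As,29.42
Se,27.81
Sn,39.35
Sb,37.74
Te,36.14
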