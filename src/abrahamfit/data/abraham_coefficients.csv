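# Abraham-model process coefficients, transcribed from the published
# water-to-solvent (log P) and gas-to-solvent (log K) correlations of the
# Abraham solvation parameter model literature (Abraham / Acree solvent
# coefficient compilations; dry solvents unless marked ", wet").
# Transcription v1. Empty cell = term not active for that process.
# The two gas_to_water records are the log Kw closure correlations, one
# written in V and one in L.
system_id,process_kind,c,e,s,a,b,v,l
methanol,water_to_solvent,0.276,0.334,-0.714,0.243,-3.320,3.549,
ethanol,water_to_solvent,0.222,0.471,-1.035,0.326,-3.596,3.857,
propan-1-ol,water_to_solvent,0.139,0.405,-1.029,0.247,-3.767,3.986,
butan-1-ol,water_to_solvent,0.165,0.401,-1.011,0.056,-3.958,4.044,
pentan-1-ol,water_to_solvent,0.150,0.536,-1.229,0.141,-3.864,4.077,
octan-1-ol,water_to_solvent,-0.034,0.489,-1.044,-0.024,-4.235,4.218,
"octan-1-ol, wet",water_to_solvent,0.088,0.562,-1.054,0.034,-3.460,3.814,
propan-2-ol,water_to_solvent,0.099,0.344,-1.049,0.406,-3.827,4.033,
butan-2-ol,water_to_solvent,0.127,0.253,-0.976,0.158,-3.882,4.114,
pentan-2-ol,water_to_solvent,0.115,0.455,-1.331,0.206,-3.745,4.201,
diethyl ether,water_to_solvent,0.330,0.401,-0.814,-0.457,-4.959,4.320,
"diethyl ether, wet",water_to_solvent,0.248,0.561,-1.016,-0.226,-4.553,4.075,
tetrahydrofuran,water_to_solvent,0.207,0.372,-0.392,-0.236,-4.934,4.447,
ethyl acetate,water_to_solvent,0.328,0.369,-0.446,-0.700,-4.904,4.150,
propyl acetate,water_to_solvent,0.288,0.363,-0.474,-0.784,-4.938,4.216,
propanone,water_to_solvent,0.313,0.312,-0.121,-0.608,-4.753,3.942,
acetonitrile,water_to_solvent,0.413,0.077,0.326,-1.566,-4.391,3.364,
dimethyl sulfoxide,water_to_solvent,-0.194,0.327,0.791,1.260,-4.540,3.361,
trichloromethane,water_to_solvent,0.191,0.105,-0.403,-3.112,-3.514,4.395,
tetrachloromethane,water_to_solvent,0.199,0.523,-1.159,-3.560,-4.594,4.618,
cyclohexane,water_to_solvent,0.159,0.784,-1.678,-3.740,-4.929,4.577,
benzene,water_to_solvent,0.142,0.464,-0.588,-3.099,-4.625,4.491,
toluene,water_to_solvent,0.143,0.527,-0.720,-3.010,-4.824,4.545,
p-xylene,water_to_solvent,0.166,0.477,-0.812,-2.939,-4.874,4.532,
chlorobenzene,water_to_solvent,0.065,0.381,-0.521,-3.183,-4.700,4.614,
nitrobenzene,water_to_solvent,-0.152,0.525,0.081,-2.332,-4.494,4.187,
trifluoroethanol,water_to_solvent,0.395,-0.094,-0.594,-1.280,-1.274,3.088,
methanol,gas_to_solvent,-0.039,-0.338,1.317,3.826,1.396,,0.773
ethanol,gas_to_solvent,0.017,-0.232,0.867,3.894,1.192,,0.846
propan-1-ol,gas_to_solvent,-0.042,-0.246,0.749,3.888,1.076,,0.874
butan-1-ol,gas_to_solvent,-0.004,-0.285,0.768,3.705,0.879,,0.890
pentan-1-ol,gas_to_solvent,-0.002,-0.161,0.535,3.778,0.960,,0.900
octan-1-ol,gas_to_solvent,-0.147,-0.214,0.561,3.507,0.749,,0.943
"octan-1-ol, wet",gas_to_solvent,-0.198,0.002,0.709,3.519,1.429,,0.858
propan-2-ol,gas_to_solvent,-0.048,-0.324,0.713,4.036,1.055,,0.884
butan-2-ol,gas_to_solvent,-0.034,-0.387,0.719,3.736,1.088,,0.905
pentan-2-ol,gas_to_solvent,-0.031,-0.325,0.496,3.792,1.024,,0.934
diethyl ether,gas_to_solvent,0.288,-0.347,0.775,2.985,0.000,,0.973
"diethyl ether, wet",gas_to_solvent,0.206,-0.169,0.873,3.402,0.000,,0.882
tetrahydrofuran,gas_to_solvent,0.189,-0.347,1.238,3.289,0.000,,0.982
ethyl acetate,gas_to_solvent,0.147,-0.214,1.171,2.949,0.000,,0.928
propyl acetate,gas_to_solvent,0.129,-0.170,1.163,2.913,0.000,,0.932
propanone,gas_to_solvent,0.127,-0.387,1.733,3.060,0.000,,0.866
acetonitrile,gas_to_solvent,-0.007,-0.595,2.461,2.085,0.418,,0.738
dimethyl sulfoxide,gas_to_solvent,-0.556,-0.223,2.903,5.037,0.000,,0.719
trichloromethane,gas_to_solvent,0.157,-0.560,1.259,0.374,1.333,,0.976
tetrachloromethane,gas_to_solvent,0.217,-0.435,0.554,0.000,0.000,,1.069
cyclohexane,gas_to_solvent,0.163,-0.110,0.000,0.000,0.000,,1.013
benzene,gas_to_solvent,0.107,-0.313,1.053,0.457,0.169,,1.020
toluene,gas_to_solvent,0.121,-0.222,0.938,0.467,0.099,,1.012
p-xylene,gas_to_solvent,0.166,-0.179,0.897,0.520,0.000,,1.010
chlorobenzene,gas_to_solvent,0.053,-0.553,1.254,0.364,0.000,,1.041
nitrobenzene,gas_to_solvent,-0.296,0.092,1.707,1.147,0.443,,0.912
trifluoroethanol,gas_to_solvent,-0.092,-0.547,1.339,2.213,3.807,,0.645
water,gas_to_water_V,-0.994,0.577,2.549,3.813,4.841,-0.869,
water,gas_to_water_L,-1.271,0.822,2.743,3.904,4.814,,-0.213
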