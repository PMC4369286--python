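# Solvent metadata: Kamlet-Taft hydrogen-bond basicity beta (Marcus scale),
# density at 298 K (g/cm^3) and molar mass (g/mol). Beta drives the
# monomer/dimer classification of saturation solubilities (threshold 0.35);
# density and molar mass serve the unit conversions. Beta left empty where
# not needed (solvents without Abraham coefficients are excluded upstream).
name,beta,density_g_per_cm3,molar_mass
methanol,0.66,0.7914,32.04
ethanol,0.75,0.7893,46.07
propan-1-ol,0.90,0.8035,60.10
butan-1-ol,0.84,0.8098,74.12
pentan-1-ol,0.86,0.8144,88.15
octan-1-ol,0.81,0.8262,130.23
propan-2-ol,0.84,0.7855,60.10
butan-2-ol,0.80,0.8063,74.12
pentan-2-ol,0.80,0.8090,88.15
diethyl ether,0.47,0.7134,74.12
tetrahydrofuran,0.55,0.8892,72.11
ethyl acetate,0.45,0.9003,88.11
propyl acetate,0.40,0.8878,102.13
propanone,0.43,0.7845,58.08
acetonitrile,0.40,0.7857,41.05
dimethyl sulfoxide,0.76,1.1004,78.13
trichloromethane,0.10,1.4832,119.38
tetrachloromethane,0.10,1.5940,153.82
cyclohexane,0.00,0.7739,84.16
benzene,0.10,0.8765,78.11
toluene,0.11,0.8669,92.14
p-xylene,0.12,0.8611,106.17
chlorobenzene,0.07,1.1058,112.56
nitrobenzene,0.30,1.2037,123.11
trifluoroethanol,0.00,1.3830,100.04
water,0.47,0.9970,18.02
pentachloroethane,,1.6796,202.29
"1,1,2,2-tetrachloroethane",,1.5953,167.85
tetrachloroethylene,,1.6227,165.83
trichloroethylene,,1.4642,131.39
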