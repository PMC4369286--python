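# Saturation solubilities of trans-cinnamic acid at 298.15 K (mol/L),
# replicate-averaged Open Notebook Science Challenge + literature values.
# Source: doi:10.1186/s13065-015-0080-9 (CC0 solubility data).
# The xylene entry is recorded as m-xylene in the source solubility table
# but is fitted with p-xylene coefficients in the source fit tables; it is
# canonicalised to p-xylene here.
solvent,kind,value,unit,temperature_C,source
water,solubility,0.004,molarity,25,ons_challenge_mean
cyclohexane,solubility,0.027,molarity,25,ons_challenge_mean
tetrachloromethane,solubility,0.167,molarity,25,ons_challenge_mean
trifluoroethanol,solubility,0.168,molarity,25,ons_challenge_mean
p-xylene,solubility,0.201,molarity,25,ons_challenge_mean
toluene,solubility,0.253,molarity,25,ons_challenge_mean
acetonitrile,solubility,0.263,molarity,25,ons_challenge_mean
tetrachloroethylene,solubility,0.277,molarity,25,ons_challenge_mean
benzene,solubility,0.303,molarity,25,ons_challenge_mean
chlorobenzene,solubility,0.314,molarity,25,ons_challenge_mean
nitrobenzene,solubility,0.429,molarity,25,ons_challenge_mean
octan-1-ol,solubility,0.537,molarity,25,ons_challenge_mean
diethyl ether,solubility,0.575,molarity,25,ons_challenge_mean
trichloroethylene,solubility,0.590,molarity,25,ons_challenge_mean
propyl acetate,solubility,0.609,molarity,25,ons_challenge_mean
pentachloroethane,solubility,0.617,molarity,25,ons_challenge_mean
butan-2-ol,solubility,0.705,molarity,25,ons_challenge_mean
pentan-1-ol,solubility,0.725,molarity,25,ons_challenge_mean
butan-1-ol,solubility,0.735,molarity,25,ons_challenge_mean
ethyl acetate,solubility,0.775,molarity,25,ons_challenge_mean
pentan-2-ol,solubility,0.922,molarity,25,ons_challenge_mean
propan-1-ol,solubility,0.934,molarity,25,ons_challenge_mean
propan-2-ol,solubility,0.967,molarity,25,ons_challenge_mean
trichloromethane,solubility,1.034,molarity,25,ons_challenge_mean
"1,1,2,2-tetrachloroethane",solubility,1.149,molarity,25,ons_challenge_mean
ethanol,solubility,1.167,molarity,25,ons_challenge_mean
propanone,solubility,1.337,molarity,25,ons_challenge_mean
methanol,solubility,1.384,molarity,25,ons_challenge_mean
tetrahydrofuran,solubility,2.367,molarity,25,ons_challenge_mean
dimethyl sulfoxide,solubility,8.423,molarity,25,ons_challenge_mean
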