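# Published observed and fitted values for trans-cinnamic acid MONOMER in
# the 16 polar solvents: log Ps (water->solvent) and log Cs (molar
# solubility), both calc and obs. Reference expectations for the
# replication pipeline, never inputs to it.
# Source: doi:10.1186/s13065-015-0080-9.
solvent,calc_log_ps,obs_log_ps,calc_log_cs,obs_log_cs
methanol,2.499,2.541,0.099,0.141
ethanol,2.515,2.467,0.115,0.067
propan-1-ol,2.381,2.370,-0.019,-0.030
butan-1-ol,2.278,2.266,-0.122,-0.134
pentan-1-ol,2.311,2.260,-0.089,-0.140
octan-1-ol,2.159,2.130,-0.241,-0.270
propan-2-ol,2.371,2.385,-0.029,-0.015
butan-2-ol,2.293,2.248,-0.107,-0.152
pentan-2-ol,2.313,2.365,-0.087,-0.035
diethyl ether,2.174,2.160,-0.226,-0.240
tetrahydrofuran,2.786,2.774,0.386,0.374
ethyl acetate,2.228,2.289,-0.172,-0.111
propyl acetate,2.158,2.185,-0.242,-0.215
propanone,2.400,2.526,0.000,0.126
acetonitrile,1.653,1.820,-0.747,-0.580
dimethyl sulfoxide,3.497,3.326,1.097,0.925
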