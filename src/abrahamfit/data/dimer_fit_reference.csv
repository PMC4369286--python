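# Published observed and fitted values for trans-cinnamic acid DIMER in
# the 9 non-polar solvents. Reference expectations for the replication
# pipeline, never inputs to it.
# Source: doi:10.1186/s13065-015-0080-9.
solvent,calc_log_ps,obs_log_ps,calc_log_cs,obs_log_cs
trichloromethane,5.598,5.672,-0.059,0.015
tetrachloromethane,4.870,4.880,-0.787,-0.777
cyclohexane,4.264,4.088,-1.393,-1.569
benzene,5.125,5.138,-0.532,-0.519
toluene,5.045,5.060,-0.612,-0.597
p-xylene,4.826,4.960,-0.831,-0.697
chlorobenzene,5.162,5.154,-0.495,-0.503
nitrobenzene,5.285,5.289,-0.372,-0.368
trifluoroethanol,4.921,4.882,-0.736,-0.775
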