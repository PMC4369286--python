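# Direct water-to-solvent partition coefficients (log Ps) for
# trans-cinnamic acid monomer, measured at or extrapolated to low solute
# concentration (Bio-Loom compilation).
# Source: doi:10.1186/s13065-015-0080-9.
solvent,kind,value,unit,temperature_C,source
"octan-1-ol, wet",direct_log_p,2.13,log_p,25,bioloom
trichloromethane,direct_log_p,1.20,log_p,25,bioloom
tetrachloromethane,direct_log_p,0.40,log_p,25,bioloom
cyclohexane,direct_log_p,-0.25,log_p,25,bioloom
"diethyl ether, wet",direct_log_p,1.92,log_p,25,bioloom
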