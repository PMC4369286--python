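# Published Abraham solute descriptors for monomeric and dimeric
# trans-cinnamic acid (reference expectations for best-effort replication;
# N and SD refer to the full published equation sets).
# Source: doi:10.1186/s13065-015-0080-9.
species,E,S,A,B,V,L,log_kw,n,sd
monomer,1.14,1.12,0.61,0.50,1.1705,5.79,6.14,45,0.100
dimer,1.68,1.07,0.24,0.94,2.2098,10.30,6.29,20,0.087
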