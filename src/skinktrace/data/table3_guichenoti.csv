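sample_code,location,month,transport,stage,cargo,svl_mm,adult,alive,predicted_origin,confirmed_origin,haplotype,group_size
LDN65,Auckland/Rotorua,April,Air,Post-border,Personal effects,32,N,Alive,Bega NSW,NSW/VIC border region,GNZ1,1
LDN66,Auckland,May,Sea,Post-border,Shipping container (ceramics),42,Y,Alive,Adelaide,Adelaide,GNZ2,1
LDN67,Auckland/Rotorua,December,Sea,Post-border,Shipping container (household effects),44,Y,Alive,Eden NSW,NSW/VIC border region,GNZ3,1
LDN229,Wellington,February,Sea,Border,Shipping container,18,N,Alive,Adelaide or Melbourne,Melbourne region,GNZ4,8
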