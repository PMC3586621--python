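sample_code,location,month,transport,stage,cargo,svl_mm,adult,alive,predicted_origin,confirmed_origin,haplotype
LDN01,Wellington,October,Air,Post-border,Personal effects,28,N,Alive,Sydney,Sydney,MAF01
LDN06,Auckland,March,Sea,Post-border,"Shipping container (cosmetics, food)",30,N,Alive,Sydney,Sydney,MAF05
LDN07,Auckland,June,Air,Border,Personal effects,39,Y,Alive,Brisbane,Gold Coast-Lamington NP,MAF06
LDN23,Auckland,June,Sea,Post-border,Shipping container (light fittings),30,N,Alive,North Sydney (Brookvale),North NSW coast-Wyong,MAF13
LDN26,Wellington,August,Sea,Post-border,Shipping container (household effects),34,N,Alive,Gold Coast,Gold Coast-Lamington NP,MAF16
LDN40,Auckland,October,Air,Border,Personal effects,35,Y,Alive,Sydney?,Brisbane (South),MAF17
LDN47,Tauranga,April,Air,Post-border,Personal effects,26,N,Alive,Caboolture,Brisbane (North),MAF18
LDN57,Christchurch,April,Air,Post-border,Personal effects,32,N,Alive,Brisbane,Brisbane (South),MAF19
LDN62,Christchurch,August,Sea,Border,Shipping container (household effects),40,Y,Dead,Brisbane (Kingston),Gold Coast-Lamington NP,MAF20
LDN64,Christchurch,October,Sea,Border,Shipping container (household effects),37,Y,Alive,Brisbane (Samford),Brisbane (North),MAF21
LDN218,Auckland,December,Air,Post-border,Personal effects,36,Y,Alive,Unknown,Sydney,MAF10
LDN230,Wellington,May,Sea,Border,Shipping container (mixed freight),36,Y,Alive,Sydney,Sydney,MAF14
LDN231,Invercargill,June,Air,Post-border,Personal effects,35,Y,Alive,Sydney,North NSW coast-Port Macquarie,MAF15
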