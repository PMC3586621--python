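sample_code,location,month,transport,cargo_type,cargo,svl_mm,adult,alive,predicted_origin,haplotype
LDN05,Palmerston North,February,Truck,Freight,Pet food,40,Y,Dead,Auckland,MAF03/NZ1
LDN11,Havelock North,August,Truck,Freight,Building materials,39,Y,Dead,Auckland,MAF02/NZ4
LDN12,Dunedin,August,Truck or rail,Freight,Timber,35,Y,Alive,Auckland,MAF07/NZ5
LDN16,Palmerston North,October,Truck,Freight,Machinery,40,Y,Alive,Unknown,MAF02/NZ4
LDN17,Christchurch,October,Truck or rail,Freight,Steel,49,Y,Alive,Auckland,MAF08/NZ3
LDN18,Christchurch,December,Truck,Freight,Decorations,28,N,Dead,Waihi Beach,MAF03/NZ1
LDN22,Christchurch,May,Rail,Container,Mixed freight,33,N,Alive,Auckland,MAF04/NZ6
LDN24,Nelson,June,Sea,Shipping container,Household effects,44,Y,Alive,Auckland,MAF09/NZ2
LDN29,Palmerston North,October,Truck,Courier,Computer,37,Y,Alive,Auckland,MAF03/NZ1
LDN30,Palmerston North,October,Truck,Freight,Engine parts,30,N,Alive,Auckland,MAF03/NZ1
LDN33,Christchurch,May,Sea,Shipping container,Beverages,40,Y,Alive,Auckland,MAF03/NZ1
LDN37,Christchurch,July,Truck,Freight,Electrical fittings,39,Y,Alive,Auckland,MAF03/NZ1
LDN45,Palmerston North,February,Truck,Freight,Building materials,38,Y,Alive,Auckland,MAF08/NZ3
LDN49,Palmerston North,May,Truck,Freight,Pipe fittings,36,Y,Alive,Auckland,MAF08/NZ3
LDN51,Porirua,July,Truck,Freight,Vegetables,22,N,Alive,Auckland,MAF03/NZ1
LDN58,New Plymouth,May,Truck,Freight,New car,37,Y,Alive,Auckland,MAF03/NZ1
LDN61,Christchurch,June,Rail or sea,Container,Unknown,38,Y,Alive,Auckland,MAF03/NZ1
LDN68,Napier,March,Truck,Freight,Plasticware,14,N,Dead,Auckland,MAF09/NZ2
LDN217,Dunedin,November,Truck,Freight,Mail,30,N,Alive,Unknown,MAF03/NZ1
LDN219,Napier,December,Truck,Freight,Mail,27,N,Alive,Auckland,MAF11
LDN223,Palmerston North,October,Unknown,Unknown,Unknown,34,N,Alive,Unknown,MAF08/NZ3
LDN224,Stratford,October,Truck,Freight,Ceramics,26,N,Alive,Auckland,MAF08/NZ3
LDN225,Rotorua,November,Truck,Freight,Beverages,39,Y,Dead,Auckland,MAF12
LDN232,New Plymouth,July,Truck,Freight,Steel,40,Y,Alive,Auckland,MAF03/NZ1
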