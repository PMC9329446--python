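code,taxon_class,T1,T2,T3,origin
Thetra,gastropod,1,0,0,NAT
Vivace,gastropod,0,0,1,AIS
Bitten,gastropod,0,0,1,NAT
Litnat,gastropod,1,0,0,NAT
Valpis,gastropod,0,1,1,NAT
Galtru,gastropod,0,1,1,NAT
Stacor,gastropod,0,0,1,NAT
Radaur,gastropod,0,1,1,NAT
Lymsta,gastropod,0,1,1,NAT
Phyacu,gastropod,0,1,1,AIS
Placor,gastropod,0,1,1,NAT
Plapla,gastropod,0,1,1,NAT
Batcon,gastropod,0,0,1,NAT
Gyralb,gastropod,0,1,1,NAT
Armcris,gastropod,0,0,1,NAT
Fercal,gastropod,0,0,1,AIS
Ancflu,gastropod,1,1,1,NAT
Unipic,bivalve,0,0,1,NAT
Unicra,bivalve,1,0,1,NAT
Anocyg,bivalve,0,1,0,NAT
Anoana,bivalve,1,0,0,NAT
Sinwoo,bivalve,0,0,1,AIS
Corflu,bivalve,0,0,1,AIS
Muslac,bivalve,0,1,1,NAT
Piscas,bivalve,1,1,1,NAT
Pisnit,bivalve,0,0,1,NAT
Pismil,bivalve,1,0,0,NAT
Drepol,bivalve,0,0,1,AIS
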