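compound,threshold_ug_per_kg,chemical_class,descriptor
Pentanal,12.00,aldehyde,
Hexanal,4.00,aldehyde,grassy at low concentration; fishy at high
Heptanal,3.00,aldehyde,
Octanal,1.40,aldehyde,sweet orange; honey
Nonanal,1.00,aldehyde,plastic; fishy
Benzaldehyde,3.00,aldehyde,almond; bitter almond; peach kernel
Isopropyl Alcohol,40000.00,alcohol,
Ethanol,8.00,alcohol,
2-Butanol,43000.00,alcohol,
1-Octen-3-ol,1.00,alcohol,mushroom
1-Heptanol,3.00,alcohol,
"4-Heptanol, 2,6-dimethyl-",1300.00,alcohol,
Benzyl alcohol,1.20,alcohol,
"5-Hepten-2-ol,6-methyl-",2000.00,alcohol,
1-Octen-3-one,0.05,ketone,
"Butanoic acid, ethyl ester",0.10,ester,fruity
"Butanoic acid, 2-methyl-, ethyl ester",0.01,ester,fruity
"Butanoic acid, 3-methyl-, ethyl ester",0.01,ester,fruity
"Hexanoic acid, ethyl ester",0.30,ester,pineapple-like fruity
"Acetic acid, 2-phenylethyl ester",3000.00,ester,
"Hexadecanoic acid, ethyl ester",2000.00,ester,
"Octanoic acid, methyl ester",200.00,ester,
Tetradecanoic acid,10000.00,acid,
n-Hexadecanoic acid,10000.00,acid,
Pyrazine,175000.00,other,
Pyrrole,20000.00,other,
"Ethanone, 1-(1H-pyrrol-2-yl)-",170000.00,other,
Caffeine,29000.00,other,
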