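compound,relative_content_percent,roav_reported
Pentanal,1.2274,2.3998
Hexanal,4.6181,27.0866
Heptanal,0.9151,7.1566
Octanal,0.6394,10.7155
Nonanal,0.1004,2.3544
Benzaldehyde,1.6205,12.6729
Isopropyl Alcohol,0.0010,5.7935e-7
Ethanol,1.1285,3.3096
2-Butanol,0.0324,1.7704e-5
1-Octen-3-ol,4.2624,100.0000
1-Heptanol,0.5823,4.5535
"4-Heptanol, 2,6-dimethyl-",0.0020,3.6283e-5
Benzyl alcohol,0.0678,1.3258
"5-Hepten-2-ol,6-methyl-",0.0006,7.1909e-6
1-Octen-3-one,0.0627,29.4274
"Butanoic acid, ethyl ester",0.0104,2.4337
"Butanoic acid, 2-methyl-, ethyl ester",0.0024,5.7434
"Butanoic acid, 3-methyl-, ethyl ester",0.0033,7.7816
"Hexanoic acid, ethyl ester",0.0375,2.9309
"Acetic acid, 2-phenylethyl ester",0.0031,2.4501e-5
"Hexadecanoic acid, ethyl ester",0.0064,7.5155e-5
"Octanoic acid, methyl ester",0.0004,4.5969e-5
Tetradecanoic acid,0.0008,1.9034e-6
n-Hexadecanoic acid,0.0163,3.8225e-5
Pyrazine,0.0449,6.0243e-6
Pyrrole,0.0133,1.5546e-5
"Ethanone, 1-(1H-pyrrol-2-yl)-",0.0046,6.3212e-7
Caffeine,0.0003,2.4773e-7
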