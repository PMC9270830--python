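rank,item,salience,p_value
1,ameixa,0.2698,0.0023
2,capim santo,0.1817,0.0497
3,erva cidreira,0.1786,0.0542
4,jatobá,0.1556,0.1005
5,umburana,0.1095,0.2960
6,mastruz,0.0952,0.4211
7,algaroba,0.0873,0.5467
8,caju roxo,0.0833,0.5159
9,goiaba,0.0635,0.3864
10,limão,0.0556,0.3197
11,quixaba,0.0540,0.3040
12,beladona,0.0476,0.1843
13,juá,0.0476,0.1843
14,mandacaru,0.0476,0.1843
15,pinhão,0.0476,0.1843
16,umbu,0.0357,0.1309
17,boldo,0.0317,0.1001
18,sassafrás,0.0286,0.0990
19,jenipapo,0.0190,0.0417
20,aroeira,0.0095,0.0024
21,romã,0.0095,0.0024
22,laranja,0.0079,0.0000
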