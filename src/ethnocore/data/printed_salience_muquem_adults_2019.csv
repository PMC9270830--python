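rank,item,salience,p_value
1,ameixa,0.7822,0.0000
2,quixaba,0.5127,0.0000
3,aroeira,0.3877,0.0000
4,jatobá,0.3794,0.0000
5,bom nome,0.3342,0.0001
6,algaroba,0.2851,0.0020
7,sassafrás,0.2731,0.0035
8,juá,0.2452,0.0112
9,bássimo,0.2399,0.0136
10,angico,0.1933,0.0708
11,umburana de cheiro,0.1739,0.1233
12,quebra faca do sertão,0.1724,0.1282
13,caju roxo,0.1717,0.1305
14,umburana de cambão,0.1634,0.1643
15,baraúna,0.1354,0.3125
16,erva cidreira,0.1102,0.5087
17,pau d’arco roxo,0.1029,0.4531
18,pinhão brabo,0.1013,0.4412
19,mororó,0.0853,0.3180
20,mastruz,0.0818,0.2932
21,babosa,0.0796,0.2767
22,piranha,0.0779,0.2650
23,papaconha,0.0760,0.2527
24,capim santo,0.0717,0.2248
25,mandacaru,0.0569,0.1361
26,umbuzeiro,0.0508,0.1059
27,alecrim,0.0465,0.0880
28,catingueira,0.0460,0.0858
29,rabo de raposa,0.0458,0.0850
30,goiaba,0.0400,0.0638
31,jucá,0.0375,0.0536
32,jurubeba,0.0336,0.0413
33,eucalipto,0.0320,0.0373
34,velame,0.0320,0.0373
35,chumbinho de areia,0.0300,0.0334
36,canzenzo,0.0280,0.0285
37,feijão brabo,0.0262,0.0250
38,maracujá do mato,0.0243,0.0215
39,arruda,0.0231,0.0197
40,manjirioba,0.0200,0.0151
41,biratanha,0.0176,0.0112
42,canelinha,0.0169,0.0100
43,pau ferro,0.0165,0.0098
44,andu,0.0160,0.0094
45,cabeça de nego,0.0154,0.0088
46,jurema preta,0.0122,0.0052
47,jiquiri,0.0080,0.0030
48,marcela,0.0067,0.0020
49,abacate,0.0064,0.0018
50,araçá,0.0060,0.0015
51,sucupira,0.0040,0.0006
52,romã,0.0033,0.0004
53,amargoso,0.0020,0.0003
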