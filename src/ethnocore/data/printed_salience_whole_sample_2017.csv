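rank,item,salience,p_value
1,ameixa,0.4644,0.0000
2,hortelã,0.4137,0.0000
3,papaconha,0.3616,0.0000
4,jatobá,0.3590,0.0000
5,mastruz,0.3462,0.0000
6,quixaba,0.3343,0.0000
7,babosa,0.3147,0.0000
8,aroeira,0.3100,0.0000
9,juá,0.2202,0.0001
10,bássimo,0.2064,0.0006
11,umburana de cambão,0.1857,0.0029
12,umburana de cheiro,0.1853,0.0030
13,alcansus,0.1636,0.0128
14,federação,0.1620,0.0148
15,mororó,0.1422,0.0459
16,baraúna,0.1391,0.0535
17,velame,0.1249,0.1059
18,erva cidreira,0.1174,0.1468
19,jurubeba,0.1137,0.1701
20,alecrim,0.1101,0.1970
21,sassafrás,0.1065,0.2266
22,algaroba,0.1060,0.2308
23,quebra faca do sertão,0.0956,0.3310
24,arruda,0.0942,0.3454
25,bom nome,0.0918,0.3735
26,caju roxo,0.0825,0.5145
27,carrapixo de boi,0.0751,0.4242
28,pau d’arco,0.0734,0.4026
29,romã,0.0608,0.2556
30,maracujá do mato,0.0591,0.2379
31,angico,0.0528,0.1754
32,sambacaité,0.0480,0.1330
33,jurema preta,0.0438,0.1017
34,mandacaru,0.0429,0.0953
35,moleque duro,0.0408,0.0818
36,melancia,0.0405,0.0802
37,eucalipto,0.0394,0.0746
38,catingueira,0.0378,0.0651
39,manjirioba,0.0374,0.0625
40,capim santo,0.0359,0.0555
41,capeba,0.0324,0.0415
42,quina quina,0.0314,0.0379
43,marmeleiro,0.0305,0.0349
44,rabo de raposa,0.0257,0.0219
45,cana de macaco,0.0246,0.0191
46,jenipapo,0.0233,0.0167
47,canelinha,0.0231,0.0163
48,ubaia,0.0188,0.0089
49,alfavaca,0.0179,0.0076
50,vassourinha,0.0173,0.0070
51,pau de leite,0.0169,0.0066
52,beladona,0.0168,0.0065
53,pau ferro,0.0168,0.0065
54,alento,0.0152,0.0051
55,cebola branca,0.0149,0.0049
56,moita de mulher,0.0143,0.0045
57,mulungu,0.0141,0.0044
58,erva doce,0.0136,0.0040
59,umbuzeiro,0.0126,0.0035
60,mata pasto,0.0125,0.0033
61,plenito,0.0122,0.0032
62,cravo,0.0117,0.0030
63,ouricuri,0.0115,0.0028
64,carcara,0.0105,0.0026
65,cambuim,0.0100,0.0023
66,jucá,0.0087,0.0018
67,folha miúda,0.0080,0.0016
68,canafistula,0.0055,0.0012
69,batata de onça,0.0045,0.0009
70,urtiga,0.0040,0.0008
71,coroa de frade,0.0036,0.0008
72,pau de alho,0.0036,0.0008
73,cabacinho,0.0035,0.0008
74,endro,0.0034,0.0008
75,quebra pedra,0.0034,0.0008
76,biratanha,0.0033,0.0008
77,agase,0.0030,0.0008
78,pinhão brabo,0.0029,0.0007
79,aveloz,0.0027,0.0007
80,espinheiro,0.0011,0.0002
81,maracujá,0.0011,0.0002
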