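rank,item,salience,p_value
1,ameixa,0.5347,0.0000
2,quixaba,0.3373,0.0000
3,papaconha,0.3193,0.0000
4,aroeira,0.2977,0.0000
5,jatobá,0.2803,0.0000
6,mastruz,0.2584,0.0000
7,mororó,0.1929,0.0028
8,alcansus,0.1790,0.0067
9,erva cidreira,0.1690,0.0125
10,babosa,0.1596,0.0228
11,bom nome,0.1477,0.0452
12,hortelã,0.1429,0.0579
13,angico,0.1376,0.0760
14,umburana de cambão,0.1374,0.0766
15,bássimo,0.1359,0.0820
16,umburana de cheiro,0.1172,0.1861
17,sassafrás,0.1153,0.2011
18,quebra faca do sertão,0.1084,0.2595
19,algaroba,0.0882,0.4707
20,capim santo,0.0832,0.4714
21,jurubeba,0.0794,0.4239
22,juá,0.0779,0.4043
23,federação,0.0742,0.3605
24,jenipapo,0.0701,0.3128
25,caju roxo,0.0677,0.2845
26,arruda,0.0673,0.2797
27,baraúna,0.0614,0.2164
28,velame,0.0564,0.1711
29,eucalipto,0.0562,0.1697
30,catingueira,0.0532,0.1441
31,jurema preta,0.0518,0.1325
32,pau d’arco roxo,0.0474,0.0986
33,alecrim,0.0445,0.0819
34,alento,0.0406,0.0627
35,jucá,0.0396,0.0587
36,capeba,0.0372,0.0476
37,pau de leite,0.0372,0.0476
38,rabo de raposa,0.0371,0.0472
39,maracujá do mato,0.0298,0.0252
40,melancia,0.0298,0.0252
41,sambacaité,0.0279,0.0207
42,moita de mulher,0.0273,0.0192
43,quebra pedra,0.0257,0.0164
44,alfavaca,0.0256,0.0161
45,mulungu,0.0235,0.0132
46,manjirioba,0.0231,0.0125
47,manjericão,0.0216,0.0104
48,boldo,0.0204,0.0087
49,coroa de frade,0.0168,0.0047
50,facheiro,0.0165,0.0045
51,cambuim,0.0164,0.0045
52,canafistula,0.0159,0.0043
53,carrapixo de boi,0.0155,0.0041
54,marmeleiro,0.0154,0.0041
55,batata de purga,0.0148,0.0036
56,folha miúda,0.0148,0.0036
57,ouricuri,0.0141,0.0034
58,umbuzeiro,0.0141,0.0034
59,biratanha,0.0122,0.0028
60,canzenzo,0.0122,0.0028
61,cana de macaco,0.0102,0.0019
62,mijo de ovelha,0.0099,0.0018
63,romã,0.0099,0.0018
64,vassourinha,0.0097,0.0018
65,espada,0.0094,0.0017
66,maracujá,0.0094,0.0017
67,melão de são caetano,0.0094,0.0017
68,canelinha,0.0093,0.0017
69,louco,0.0089,0.0016
70,cabeça de nego,0.0078,0.0012
71,beladona,0.0068,0.0009
72,marcela,0.0068,0.0009
73,caroá,0.0056,0.0006
74,pau ferro,0.0051,0.0004
75,pau d’arco branco,0.0043,0.0004
76,maçaranduba,0.0041,0.0003
77,cabuci,0.0031,0.0002
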