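sample_id,name,dating_start,dating_end,sex,age_class,pipe,shaman,anthracosis,theobromine,caffeine,theophylline,nicotine,cotinine
4,Djoussulen,1600,1700,M,unknown,none,false,unassessed,32,ND,ND,17,13
46,Kureleekh 2,1700,1750,F,>50,none,false,yes,ND,11,13,171,35
37,Urun myran,1700,1750,M,30-50,none,false,unassessed,ND,ND,ND,15,24
10,Tysarastaakh 2A,1700,1750,F,30-50,none,false,unassessed,ND,ND,ND,13,31
3,Sergueleakh,1700,1750,F,15-30,none,false,unassessed,ND,ND,ND,68,39
38,Ordiogone 1,1700,1750,M,>50,none,false,unassessed,ND,ND,ND,28,67
13,Mounour urekh 1,1700,1750,M,>50,none,false,unassessed,ND,ND,ND,126,195
29,Arbre 1 Sujet 1,1700,1750,M,30-50,simple,false,unassessed,ND,ND,ND,194,12055
45,Haras,1700,1750,F,0-15,none,true,unassessed,388,33,16,47,22
36,Alyy,1700,1750,M,unknown,simple,false,yes,270,61,112,42,173
26,Arbre 1 Sujet3,1700,1750,F,30-50,none,false,unassessed,219,48,42,89,89
27,Arbre 3,1700,1750,F,30-50,simple,false,unassessed,124,16,ND,124,612
8,Kyys,1700,1750,F,15-30,none,true,unassessed,123,26,ND,801,201
12,Arbre chamanique femme Sujet 2,1700,1750,F,15-30,none,false,yes,103,55,ND,1196,702
44,Eletcheï 2,1700,1750,F,0-15,none,true,unassessed,84,ND,ND,92,92
11,Tysarastaakh 2E,1700,1750,M,0-15,none,false,unassessed,38,51,19,ND,58
20,Atyyr meïte 1,1700,1750,M,15-30,none,false,unassessed,37,ND,ND,19,42
17,Ebuguey 1,1700,1750,F,30-50,none,false,unassessed,11,12,ND,20,10
40,Boulgounniakh 2,1700,1750,F,30-50,none,true,unassessed,10,12,ND,46,40
21,KouraNDkh 1,1750,1800,M,15-30,simple,false,unassessed,ND,14,27,84,728
16,Sobolokh 1,1750,1800,F,30-50,none,false,unassessed,ND,76,ND,32,15
30,Ordiogone 2,1750,1800,M,unknown,none,false,yes,ND,ND,60,210,2083
22,Uettekh,1750,1800,F,0-15,none,false,unassessed,ND,ND,ND,37,57
24,Mounour urekh 1 bis,1750,1800,F,>50,simple,false,unassessed,ND,ND,ND,127,82
43,Sordonokh 1,1750,1800,F,15-30,none,true,yes,387,19,ND,58,146
1,Eletcheï 1,1750,1800,F,30-50,none,false,yes,244,ND,ND,33,312
35,Kerdugen 1,1750,1800,M,15-30,none,false,unassessed,228,252,57,66,313
19,Batta tchara,1750,1800,M,>50,none,false,unassessed,207,15,ND,31,80
41,Bakhtakh 1,1750,1800,F,>50,special,false,yes_with_emphysema,104,93,ND,628,14749
34,Tomtor 1,1750,1800,M,30-50,none,false,unassessed,50,19,11,37,106
23,Arbre 2 (okht2),1750,1800,F,>50,none,false,unassessed,27,ND,ND,99,82
28,Bouogaryma 2,1750,1800,F,>50,none,false,unassessed,17,30,ND,20,194
47,Ottokh 1,1800,1850,F,>50,none,false,unassessed,ND,10,ND,249,126
39,Ottokh 2,1800,1850,F,>50,none,false,unassessed,ND,15,ND,88,433
14,Omouk 1,1800,1850,F,30-50,simple,false,unassessed,4712,9304,1929,214,4528
9,Byljasyk 1,1800,1850,M,0-15,none,false,unassessed,495,791,56,125,388
15,Omouk 3,1800,1850,F,15-30,none,false,unassessed,285,692,116,72,293
42,Otchugouï 1,1800,1850,F,30-50,none,false,unassessed,82,ND,ND,66,100
32,Tomtor 2,1800,1850,M,15-30,none,false,unassessed,75,55,19,ND,46
7,Ous siré 1,1800,1850,M,15-30,simple,false,unassessed,72,14,12,811,153
25,TargaND 1,1800,1850,Indet,0-15,none,false,unassessed,49,ND,ND,ND,10
31,BalagaNDkh 3,1850,1900,M,30-50,none,false,unassessed,ND,17,10,21,46
2,Oyogosse tumula 2 Sujet A,1850,1900,F,15-30,none,false,unassessed,ND,ND,29,14,39
33,Touora urekh 1,1850,1900,F,30-50,simple,false,unassessed,1716,4464,607,192,562
18,Ken ébé 3,1850,1900,M,0-15,none,false,unassessed,323,689,76,145,52
5,Tchenkeloeil,1850,1900,Indet,0-15,none,false,unassessed,251,ND,ND,25,28
6,Oyogosse tumula 2 Sujet B,1850,1900,F,15-30,imported,false,unassessed,13,26,18,ND,22
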