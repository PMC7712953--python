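participant,periventricular_mm3,subcortical_mm3,total_mm3
1,3012,281,3293
2,5853,1783,7636
3,4453,1236,5689
4,2237,172,2409
5,1483,275,1758
6,84,835,919
7,2008,410,2418
8,6317,5329,11646
9,2014,198,2212
10,920,272,1192
11,1187,4708,5895
12,1878,528,2406
13,939,1055,1994
14,8801,22727,31528
15,1287,1273,2560
16,4895,1301,6196
17,13362,16489,29851
18,2445,674,3119
19,15436,21103,36539
20,1621,541,2162
21,3973,1234,5207
22,5643,2537,8180
23,4493,1513,6006
24,7378,6072,13450
25,2022,317,2339
26,6421,3796,10217
27,8271,3815,12086
28,2990,1324,4314
29,5248,2967,8215
30,3156,1507,4663
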