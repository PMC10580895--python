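run,ph,temperature_c,oil_g,agitation_rpm,time_d,response_g_l
1,6,30,6.5,200,7,5.93
2,5,35,6.5,150,5,6.07
3,7,35,6.5,150,9,4.56
4,5,35,4.5,150,9,5.85
5,6,35,5.5,200,7,8.02
6,7,35,4.5,150,5,5.50
7,5,35,4.5,250,5,6.28
8,5,25,6.5,250,5,5.37
9,7,25,6.5,150,5,2.39
10,7,35,4.5,250,9,2.53
11,7,25,4.5,150,9,5.25
12,7,25,4.5,250,5,2.93
13,5,30,5.5,200,7,5.05
14,7,25,6.5,250,9,4.50
15,6,30,5.5,200,7,4.47
16,5,25,4.5,250,9,4.41
17,5,25,4.5,150,5,5.88
18,6,30,5.5,250,7,3.84
19,6,30,5.5,200,5,4.48
20,7,35,6.5,250,5,6.45
21,5,25,6.5,150,9,3.45
23,5,35,6.5,250,9,4.53
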