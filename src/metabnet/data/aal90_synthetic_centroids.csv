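region_id,name,hemisphere,x_mm,y_mm,z_mm
1,PreCG.L,L,-39,-6,51
2,PreCG.R,R,39,-6,51
3,SFGdor.L,L,-18,35,42
4,SFGdor.R,R,18,35,42
5,ORBsup.L,L,-17,47,-13
6,ORBsup.R,R,17,47,-13
7,MFG.L,L,-33,33,35
8,MFG.R,R,33,33,35
9,ORBmid.L,L,-31,50,-10
10,ORBmid.R,R,31,50,-10
11,IFGoperc.L,L,-48,13,19
12,IFGoperc.R,R,48,13,19
13,IFGtriang.L,L,-46,30,14
14,IFGtriang.R,R,46,30,14
15,ORBinf.L,L,-36,31,-12
16,ORBinf.R,R,36,31,-12
17,ROL.L,L,-47,-8,14
18,ROL.R,R,47,-8,14
19,SMA.L,L,-5,5,61
20,SMA.R,R,5,5,61
21,OLF.L,L,-8,15,-11
22,OLF.R,R,8,15,-11
23,SFGmed.L,L,-5,49,31
24,SFGmed.R,R,5,49,31
25,ORBsupmed.L,L,-5,54,-7
26,ORBsupmed.R,R,5,54,-7
27,REC.L,L,-5,37,-18
28,REC.R,R,5,37,-18
29,INS.L,L,-35,7,3
30,INS.R,R,35,7,3
31,ACG.L,L,-4,35,14
32,ACG.R,R,4,35,14
33,DCG.L,L,-5,-15,42
34,DCG.R,R,5,-15,42
35,PCG.L,L,-5,-43,25
36,PCG.R,R,5,-43,25
37,HIP.L,L,-25,-21,-10
38,HIP.R,R,25,-21,-10
39,PHG.L,L,-21,-16,-21
40,PHG.R,R,21,-16,-21
41,AMYG.L,L,-23,-1,-17
42,AMYG.R,R,23,-1,-17
43,CAL.L,L,-7,-79,6
44,CAL.R,R,7,-79,6
45,CUN.L,L,-6,-80,27
46,CUN.R,R,6,-80,27
47,LING.L,L,-15,-68,-5
48,LING.R,R,15,-68,-5
49,SOG.L,L,-17,-84,28
50,SOG.R,R,17,-84,28
51,MOG.L,L,-32,-81,16
52,MOG.R,R,32,-81,16
53,IOG.L,L,-36,-78,-8
54,IOG.R,R,36,-78,-8
55,FFG.L,L,-31,-40,-20
56,FFG.R,R,31,-40,-20
57,PoCG.L,L,-42,-23,49
58,PoCG.R,R,42,-23,49
59,SPG.L,L,-23,-60,59
60,SPG.R,R,23,-60,59
61,IPL.L,L,-43,-46,47
62,IPL.R,R,43,-46,47
63,SMG.L,L,-56,-34,30
64,SMG.R,R,56,-34,30
65,ANG.L,L,-44,-61,36
66,ANG.R,R,44,-61,36
67,PCUN.L,L,-7,-56,48
68,PCUN.R,R,7,-56,48
69,PCL.L,L,-8,-25,70
70,PCL.R,R,8,-25,70
71,CAU.L,L,-11,11,9
72,CAU.R,R,11,11,9
73,PUT.L,L,-24,4,2
74,PUT.R,R,24,4,2
75,PAL.L,L,-18,0,0
76,PAL.R,R,18,0,0
77,THA.L,L,-11,-18,8
78,THA.R,R,11,-18,8
79,HES.L,L,-42,-19,10
80,HES.R,R,42,-19,10
81,STG.L,L,-53,-21,7
82,STG.R,R,53,-21,7
83,TPOsup.L,L,-40,15,-20
84,TPOsup.R,R,40,15,-20
85,MTG.L,L,-56,-34,-2
86,MTG.R,R,56,-34,-2
87,TPOmid.L,L,-36,15,-34
88,TPOmid.R,R,36,15,-34
89,ITG.L,L,-50,-28,-23
90,ITG.R,R,50,-28,-23
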