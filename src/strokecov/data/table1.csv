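no,id,age,gender,side,etiology,nih_b,nih_m3,nih_m9,mrs_b,mrs_m3,mrs_m9,hd_b,hd_m3,hd_m9,pso_b,pso_m3,pso_m9,tor_b,tor_m3,tor_m9
1,p01,77,M,L,UN,4,2,1,2,1,1,31,40,41,9.7,7.9,5.7,30,30,30
2,p02,50,M,R,OC,7,1,0,4,1,0,6,54,63,0.0,6.0,6.2,25,28,30
3,p03,78,M,R,LAD,5,5,3,3,2,2,15,17,42,13.5,11.1,9.1,28,29,27
4,p05,80,M,L,LAD,2,3,1,2,1,1,42,42,37,10.6,6.5,8.4,30,30,30
5,p06,53,F,R,LAD,6,3,3,3,2,1,11,9,19,29.9,10.1,14.9,0,0,0
6,p07,78,F,R,CE,4,2,2,2,1,1,18,21,21,14.0,7.5,7.1,0,12,24
7,p09,70,F,R,CE,3,2,0,2,1,0,21,31,34,9.1,8.5,6.0,29,30,30
8,p11,41,F,L,LAD,3,2,0,1,0,0,32,37,39,5.6,4.0,5.11,24,30,30
9,p12,54,M,R,UN,4,2,1,3,1,0,14,33,38,8.5,5.5,5.2,30,30,30
10,p15,54,M,L,LAD,6,4,1,3,1,1,10,24,33,38.8,13.1,11.1,0,6,10
11,p16,73,M,R,OC,4,2,0,2,1,0,51,55,55,7.3,4.9,5.3,26,29,30
12,p17,58,M,L,CE,4,2,0,3,0,0,20,39,48,11.5,4.3,4.7,30,29,30
13,p20,70,M,L,CE,6,4,2,3,1,1,24,35,42,12.9,9.7,9.3,0,6,10
14,p24,74,M,R,CE,4,1,0,1,0,0,34,49,50,14.3,6.9,5.1,28,30,30
15,p25,49,M,R,CE,3,2,1,2,1,0,49,59,67,12.3,5.3,5.9,0,6,10
16,p26,44,M,L,CE,3,1,0,1,0,0,9,33,50,11.5,6.0,5.1,30,30,30
17,p30,63,M,L,CE,4,1,1,3,0,0,43,41,45,10.6,6.3,6.3,30,30,30
18,p31,63,M,L,UN,5,0,0,2,0,0,30,48,44,5.3,4.2,4.7,30,30,30
19,p33,75,M,R,LAD,3,2,2,2,1,1,3,14,22,0.0,18.8,11.5,12,28,30
20,p35,78,M,L,LAD,5,3,2,3,1,1,23,48,40,10.1,6.8,6.1,30,30,30
21,p36,60,M,L,CE,4,1,1,3,1,1,31,40,41,18.2,8.0,6.6,30,30,30
22,p37,75,M,R,OC,4,2,1,2,1,1,0,27,32,0.0,8.6,10.4,4,23,25
23,p38,77,M,L,LAD,5,2,2,3,1,1,10,21,23,26.9,10.9,8.3,29,30,30
24,p41,51,M,R,CE,2,1,0,2,1,1,36,41,52,7.1,5.1,4.8,30,30,30
25,p42,64,M,R,LAD,1,0,0,2,0,0,14,33,35,18.9,7.1,7.4,29,30,30
26,p43,82,M,L,LAD,3,3,2,2,2,1,17,10,18,16.8,21.4,13.9,20,22,25
27,p44,67,M,R,UN,11,10,9,4,3,3,15,15,41,52.3,45.1,12.3,3,4,2
28,p45,53,M,R,LAD,11,9,4,5,3,2,0,10,17,0.0,45.5,19.9,0,1,3
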