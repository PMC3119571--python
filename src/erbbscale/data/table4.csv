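homology_row,section,kinase,state,res_i,res_j,bond_type
1,aC-helix A-loop,ErbB4,inactive,E739,R841,salt-bridge
2,aC-helix A-loop,EGFR,active,E734,K851,salt-bridge
2,aC-helix A-loop,ErbB2,active,E766,K883,salt-bridge
2,aC-helix A-loop,ErbB4,active,E739,K856,salt-bridge
3,aC-helix A-loop,EGFR,active,D737,K836,h-bond
3,aC-helix A-loop,ErbB2,active,D769,R868,h-bond
3,aC-helix A-loop,ErbB4,inactive,D742,R841,h-bond
4,aC-helix A-loop,EGFR,active,E738,F832,h-bond
4,aC-helix A-loop,ErbB4,active,E743,F837,h-bond
5,aC-helix A-loop,EGFR,inactive,E738,K836,salt-bridge
5,aC-helix A-loop,ErbB4,inactive,E743,R841,salt-bridge
6,A-loop C-loop,ErbB2,inactive,G865,V842,h-bond
7,A-loop C-loop,ErbB4,inactive,G838,R817,h-bond
8,A-loop C-loop,EGFR,active,L834,R812,h-bond
8,A-loop C-loop,ErbB2,active,L866,R844,h-bond
8,A-loop C-loop,ErbB4,active,L839,R817,h-bond
9,A-loop C-loop,EGFR,inactive,L834,D813,h-bond
10,A-loop C-loop,EGFR,active,K836,V810,h-bond
10,A-loop C-loop,ErbB2,active,R868,V842,h-bond
10,A-loop C-loop,ErbB4,active,R841,V815,h-bond
11,A-loop C-loop,ErbB3,inactive,D838,R814,salt-bridge
12,A-loop C-loop,EGFR,active,E848,R812,salt-bridge
13,A-loop C-loop,EGFR,inactive,K851,R812,h-bond
14,C-loop C-loop,ErbB2,active,H843,D845,h-bond
14,C-loop C-loop,ErbB3,inactive,H813,N815,h-bond
15,C-loop C-loop,EGFR,inactive,R812,D813,salt-bridge
15,C-loop C-loop,ErbB2,inactive,R844,D845,h-bond
16,C-loop C-loop,EGFR,active,D813,R817,salt-bridge
16,C-loop C-loop,ErbB2,active,D845,R849,h-bond
16,C-loop C-loop,ErbB4,active,D818,R822,salt-bridge
17,C-loop C-loop,EGFR,active,D813,N818,h-bond
17,C-loop C-loop,ErbB3,inactive,N815,N820,h-bond
18,C-loop C-loop,EGFR,active,A815,N818,h-bond
18,C-loop C-loop,ErbB2,active,A847,N850,h-bond
18,C-loop C-loop,ErbB4,active,A820,N823,h-bond
18,C-loop C-loop,EGFR,inactive,A815,N818,h-bond
18,C-loop C-loop,ErbB2,inactive,A847,N850,h-bond
18,C-loop C-loop,ErbB3,inactive,A817,N820,h-bond
19,C-loop C-loop,ErbB2,active,A848,V851,h-bond
20,aC-helix,ErbB2,active,A763,S760,h-bond
21,aC-helix,ErbB2,active,E766,R756,h-bond
22,aC-helix,EGFR,active,E738,K721,salt-bridge
22,aC-helix,ErbB2,active,E770,K753,salt-bridge
22,aC-helix,ErbB4,active,E743,K726,salt-bridge
23,aC-helix,EGFR,inactive,M742,L753,h-bond
23,aC-helix,ErbB2,inactive,M774,L785,h-bond
23,aC-helix,ErbB4,inactive,M747,L758,h-bond
24,aC-helix,EGFR,active,A743,L679,h-bond
24,aC-helix,ErbB4,active,A748,Q684,h-bond
25,aC-helix,ErbB4,inactive,A748,R757,h-bond
26,A-loop,ErbB4,active,D836,K726,h-bond
26,A-loop,ErbB2,inactive,D863,K753,salt-bridge
26,A-loop,ErbB3,inactive,D833,K723,salt-bridge
26,A-loop,ErbB4,inactive,D836,K726,salt-bridge
27,A-loop,ErbB4,active,D836,T835,h-bond
28,A-loop,EGFR,active,L838,R808,h-bond
28,A-loop,ErbB2,active,L870,R840,h-bond
28,A-loop,ErbB4,active,L843,R813,h-bond
29,A-loop,ErbB2,active,D871,R840,h-bond
30,A-loop,ErbB3,inactive,D844,K853,salt-bridge
31,A-loop,ErbB4,active,K848,T873,h-bond
32,A-loop,EGFR,active,K843,D932,salt-bridge
32,A-loop,ErbB4,active,K848,D937,h-bond
33,A-loop,ErbB2,active,E876,R898,h-bond
34,A-loop,ErbB4,active,E849,K871,h-bond
35,A-loop,EGFR,active,Y845,Y867,h-bond
35,A-loop,ErbB4,active,Y850,F872,h-bond
36,A-loop,ErbB4,active,A852,R870,h-bond
37,A-loop,ErbB2,active,D880,R897,salt-bridge
37,A-loop,ErbB4,active,D853,R870,salt-bridge
37,A-loop,EGFR,inactive,E848,R865,salt-bridge
37,A-loop,ErbB2,inactive,D880,R897,salt-bridge
37,A-loop,ErbB4,inactive,D853,R870,salt-bridge
38,A-loop,ErbB4,inactive,G855,E730,h-bond
39,A-loop,ErbB2,inactive,K883,E757,h-bond
40,A-loop,ErbB4,inactive,K856,E844,salt-bridge
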