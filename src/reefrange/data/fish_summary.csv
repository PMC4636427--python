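fish_id,fl_cm,date_tagged,last_detected,area,zone,ri,resident
1,32.9,3/11/10,17/11/11,North,SZ,0.99,Y
2,34.8,2/11/10,22/04/11,East,SZ,0.41,N
3,33.6,2/11/10,17/11/11,East,SZ,1.00,Y
4,25.5,2/11/10,,East,SZ,0.00,N
5,25.9,3/11/10,10/11/10,South,SZ,0.02,N
6,26.7,3/11/10,09/11/11,South,SZ,0.62,N
7,25.6,3/11/10,13/11/11,South,SZ,0.98,Y
8,24.5,3/11/10,17/11/11,South,SZ,0.99,Y
9,25.4,2/11/10,10/11/10,East,SZ,0.01,N
10,26.3,3/11/10,16/06/11,South,SZ,0.58,N
11,29.6,3/11/10,18/11/11,South,SZ,0.99,Y
12,25.9,3/11/10,18/11/11,South,SZ,0.99,Y
13,27.4,2/11/10,28/06/11,East,SZ,0.62,N
14,27.7,3/11/10,16/11/11,South,SZ,0.99,Y
15,34.1,3/11/10,18/11/11,South,SZ,0.99,Y
16,26.4,3/11/10,,South,SZ,0.00,N
17,38.2,4/11/10,18/11/11,West,HPZ,0.92,N
18,37.8,3/11/10,01/01/12,North,HPZ,0.89,N
19,53.0,2/11/10,27/02/14,East,SZ,1.00,Y
20,57.5,3/11/10,02/12/13,North,HPZ,0.99,Y
21,42.1,3/11/10,10/02/11,West,HPZ,0.29,N
22,40.7,4/11/10,16/01/14,East,SZ,0.99,Y
23,38.6,4/11/10,03/03/12,South,SZ,0.99,Y
24,39.5,3/11/10,03/01/14,North,HPZ,0.99,Y
25,37.5,4/11/10,04/03/14,East,SZ,0.99,Y
26,49.6,3/11/10,08/12/10,West,HPZ,0.10,N
27,55.3,4/11/10,05/04/14,West,HPZ,0.99,Y
28,48.3,4/11/10,06/04/14,West,HPZ,0.99,N
29,48.6,4/11/10,11/02/12,West,HPZ,0.83,N
30,46.0,4/11/10,01/06/11,West,HPZ,0.54,N
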