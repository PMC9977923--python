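# Zachary karate club faction membership (0 = Mr. Hi's side, 1 = officers' side)
# 'flow' = Zachary's network-flow (minimum-cut) partition; 'observed' = actual post-fission club membership
node	flow	observed
0	0	0
1	0	0
2	0	0
3	0	0
4	0	0
5	0	0
6	0	0
7	0	0
8	1	0
9	1	1
10	0	0
11	0	0
12	0	0
13	0	0
14	1	1
15	1	1
16	0	0
17	0	0
18	1	1
19	0	0
20	1	1
21	0	0
22	1	1
23	1	1
24	1	1
25	1	1
26	1	1
27	1	1
28	1	1
29	1	1
30	1	1
31	1	1
32	1	1
33	1	1
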