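channel_id	anatomical_label	roi
1	Right inferior frontal gyrus	unassigned
2	Right middle frontal gyrus	rDLPFC
3	Right middle frontal gyrus	rDLPFC
4	Right middle frontal gyrus	rMPFC
5	Right superior frontal gyrus	rMPFC
6	Right middle frontal gyrus	rMPFC
7	Right superior frontal gyrus	rMPFC
8	Right middle frontal gyrus	rDLPFC
9	Right middle frontal gyrus	rDLPFC
10	Right middle frontal gyrus	rDLPFC
11	Right superior frontal gyrus	rMPFC
12	Right superior frontal gyrus	unassigned
13	Left superior frontal gyrus	lMPFC
14	Left middle frontal gyrus	lMPFC
15	Left superior frontal gyrus	lMPFC
16	Left middle frontal gyrus	lMPFC
17	Left middle frontal gyrus	lMPFC
18	Left middle frontal gyrus	lMPFC
19	Left middle frontal gyrus	lDLPFC
20	Left middle frontal gyrus	lDLPFC
21	Left middle frontal gyrus	lDLPFC
22	Left inferior frontal gyrus	unassigned
23	Left middle frontal gyrus	lDLPFC
24	Left middle frontal gyrus	lDLPFC
25	Right middle temporal gyrus	rM/STG
26	Right middle temporal gyrus	rM/STG
27	Right middle temporal gyrus	rM/STG
28	Right angular gyrus	rTPJ
29	Right angular gyrus	rTPJ
30	Right middle temporal gyrus	rM/STG
31	Right superior temporal gyrus	rM/STG
32	Right supramarginal gyrus	rIPL
33	Right superior temporal gyrus	rTPJ
34	Right angular gyrus	rTPJ
35	Right angular gyrus	rIPL
36	Right angular gyrus	rIPL
37	Left middle temporal gyrus	unassigned
38	Left middle temporal gyrus	lM/STG
39	Left middle temporal gyrus	lM/STG
40	Left angular gyrus	lTPJ
41	Left angular gyrus	lTPJ
42	Left angular gyrus	lM/STG
43	Left supramarginal gyrus	lTPJ
44	Left supramarginal gyrus	lIPL
45	Left superior temporal gyrus	lM/STG
46	Left angular gyrus	lTPJ
47	Left angular gyrus	lIPL
48	Left supramarginal gyrus	lIPL
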