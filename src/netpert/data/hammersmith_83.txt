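# Hammersmith-style 83-region parcellation (synthetic label fixture)
# basal-ganglia structures listed first; cerebellum = SUVr reference
# id	name	role
1	caudate nucleus (L)	analysis
2	caudate nucleus (R)	analysis
3	nucleus accumbens (L)	analysis
4	nucleus accumbens (R)	analysis
5	putamen (L)	analysis
6	putamen (R)	analysis
7	pallidum (L)	analysis
8	pallidum (R)	analysis
9	thalamus (L)	analysis
10	thalamus (R)	analysis
11	substantia nigra (L)	analysis
12	substantia nigra (R)	analysis
13	hippocampus (L)	analysis
14	hippocampus (R)	analysis
15	amygdala (L)	analysis
16	amygdala (R)	analysis
17	anterior temporal lobe, medial part (L)	analysis
18	anterior temporal lobe, medial part (R)	analysis
19	anterior temporal lobe, lateral part (L)	analysis
20	anterior temporal lobe, lateral part (R)	analysis
21	parahippocampal and ambient gyri (L)	analysis
22	parahippocampal and ambient gyri (R)	analysis
23	superior temporal gyrus, posterior part (L)	analysis
24	superior temporal gyrus, posterior part (R)	analysis
25	middle and inferior temporal gyrus (L)	analysis
26	middle and inferior temporal gyrus (R)	analysis
27	fusiform gyrus (L)	analysis
28	fusiform gyrus (R)	analysis
29	insula (L)	analysis
30	insula (R)	analysis
31	lateral remainder of occipital lobe (L)	analysis
32	lateral remainder of occipital lobe (R)	analysis
33	anterior cingulate gyrus (L)	analysis
34	anterior cingulate gyrus (R)	analysis
35	posterior cingulate gyrus (L)	analysis
36	posterior cingulate gyrus (R)	analysis
37	middle frontal gyrus (L)	analysis
38	middle frontal gyrus (R)	analysis
39	posterior temporal lobe (L)	analysis
40	posterior temporal lobe (R)	analysis
41	inferolateral remainder of parietal lobe (L)	analysis
42	inferolateral remainder of parietal lobe (R)	analysis
43	lateral ventricle, frontal horn and body (L)	analysis
44	lateral ventricle, frontal horn and body (R)	analysis
45	lateral ventricle, temporal horn (L)	analysis
46	lateral ventricle, temporal horn (R)	analysis
47	precentral gyrus (L)	analysis
48	precentral gyrus (R)	analysis
49	straight gyrus (L)	analysis
50	straight gyrus (R)	analysis
51	anterior orbital gyrus (L)	analysis
52	anterior orbital gyrus (R)	analysis
53	inferior frontal gyrus (L)	analysis
54	inferior frontal gyrus (R)	analysis
55	superior frontal gyrus (L)	analysis
56	superior frontal gyrus (R)	analysis
57	postcentral gyrus (L)	analysis
58	postcentral gyrus (R)	analysis
59	superior parietal gyrus (L)	analysis
60	superior parietal gyrus (R)	analysis
61	lingual gyrus (L)	analysis
62	lingual gyrus (R)	analysis
63	cuneus (L)	analysis
64	cuneus (R)	analysis
65	medial orbital gyrus (L)	analysis
66	medial orbital gyrus (R)	analysis
67	lateral orbital gyrus (L)	analysis
68	lateral orbital gyrus (R)	analysis
69	posterior orbital gyrus (L)	analysis
70	posterior orbital gyrus (R)	analysis
71	subgenual frontal cortex (L)	analysis
72	subgenual frontal cortex (R)	analysis
73	subcallosal area (L)	analysis
74	subcallosal area (R)	analysis
75	pre-subgenual frontal cortex (L)	analysis
76	pre-subgenual frontal cortex (R)	analysis
77	superior temporal gyrus, anterior part (L)	analysis
78	superior temporal gyrus, anterior part (R)	analysis
79	occipital pole (L)	analysis
80	occipital pole (R)	analysis
81	brainstem	analysis
82	corpus callosum	analysis
83	third ventricle	analysis
901	cerebellum (L)	reference
902	cerebellum (R)	reference
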