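# Published cohort life table of Pristionchus pacificus strain PS312 (N = 33),
# hanging-drop culture, 20 degC, 5e9 E. coli cells/ml.
# n0 = 33
time	D	lx	mx	lxmx
75	6	0.97	8.34	8.09
81	6	0.97	7.00	6.79
87	6	0.97	5.03	4.88
93	6	0.94	3.61	3.39
99	6	0.94	4.77	4.48
105	6	0.94	3.94	3.70
111	6	0.94	4.63	4.34
117	6	0.94	3.87	3.64
123	6	0.94	4.61	4.33
132	12	0.94	10.81	10.15
144	12	0.94	11.68	10.97
156	12	0.94	11.19	10.52
168	12	0.94	13.16	12.36
180	12	0.94	10.58	9.94
192	12	0.94	4.19	3.94
204	12	0.94	3.81	3.58
216	12	0.94	2.45	2.30
228	12	0.94	1.06	1.00
240	12	0.91	0.30	0.27
252	12	0.91	0.07	0.06
264	12	0.88	0.17	0.15
276	12	0.88	0.03	0.03
288	12	0.88	0.00	0.00
306	24	0.88	0.00	0.00
330	24	0.88	0.03	0.03
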