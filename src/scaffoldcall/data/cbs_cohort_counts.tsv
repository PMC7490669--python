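population	variant	ref_total	ref_positive	study_total	study_positive	printed_ref_rate	printed_study_rate	printed_p	note
All Ethnicities	snv	13970	24	60318	103	0.17	0.17	1
All Ethnicities	complex	13970	2948	60318	11153	21.10	18.49	<0.0001
African/African American	snv	4359	2	177	0	0.05	0	1
African/African American	complex	4359	1688	177	80	38.72	45.2	0.08
Latin American	snv	424	0	323	0	0	0
Latin American	complex	424	53	323	52	12.54	16.1	0.17	printed ref rate inconsistent with counts (53/424 = 12.50)
Ashkenazi Jewish	snv	145	0	169	0	0	0
Ashkenazi Jewish	complex	145	11	169	18	7.93	10.65	0.44	printed ref rate inconsistent with counts (11/145 = 7.59)
East Asian	snv	780	0	382	0	0	0
East Asian	complex	780	2	382	18	0.26	4.71	<0.0001
European	snv	7718	22	518	2	0.29	0.39	0.66
European	complex	7718	1057	518	71	13.7	14.29	1	printed study rate inconsistent with counts (71/518 = 13.71)
Other	snv	544	0	292	0	0	0
Other	complex	544	80	292	48	14.76	16.44	0.55	printed ref rate inconsistent with counts (80/544 = 14.71)
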