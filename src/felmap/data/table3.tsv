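angle	residues	location	H_APO_ADP	H_APO_ATP	H_ADP_ATP	bold_APO_ADP	bold_APO_ATP	bold_ADP_ATP
213	G212-E213-K214-T215	IIA	0.01	0.19	0.86	1	1	0
432	D431-N432-Q433-S434	SBD-beta	0.54	0.53	1.00	1	1	0
463	I462-N463-P464-A465	SBD-beta	0.45	0.64	0.94	1	1	0
490	K489-D490-K491-N492	SBD-beta	0.49	0.36	0.95	1	1	0
492	K491-N492-S493-G494	SBD-beta	0.57	0.62	0.93	1	1	0
494	S493-G494-K495-E496	SBD-beta	0.64	0.53	0.97	1	1	0
504	A503-S504-S505-G506	SBD-alpha	0.41	0.64	0.73	1	1	0
77	R76-F77-Q78-D79	IB	0.32	0.87	0.16	1	0	1
98	D97-N98-G99-D100	IB	0.25	0.82	0.22	1	0	1
102	A101-W102-V103-E104	IB	0.35	0.75	0.61	1	0	1
193	V192-Y193-D194-L195	IIA	0.63	0.99	0.66	1	0	1
253	L252-R253-N254-D255	IIB	0.63	0.99	0.70	1	0	1
339	I338-L339-V340-G341	IIA	0.46	0.98	0.34	1	0	1
12	T11-T12-N13-S14	IA	0.99	0.46	0.40	0	1	1
249	Q248-G249-I250-D251	IIB	0.89	0.48	0.28	0	1	1
250	G249-I250-D251-L252	IIB	0.95	0.37	0.26	0	1	1
387	V386-K387-D388-V389	linker	0.74	0.01	0.02	0	1	1
407	G406-V407-M408-T409	SBD-beta	0.87	0.43	0.43	0	1	1
408	V407-M408-T409-T410	SBD-beta	0.79	0.52	0.62	0	1	1
448	R447-A448-A449-D450	SBD-beta	0.87	0.67	0.54	0	1	1
508	L507-N508-E509-D510	SBD-alpha	0.98	0.67	0.59	0	1	1
524	A523-E524-A525-D526	SBD-alpha	0.98	0.56	0.59	0	1	1
65	N64-T65-L66-F67	IB	0.53	0.45	0.12	1	1	1
444	G443-E444-R445-K446	SBD-beta	0.64	0.19	0.68	1	1	1
464	N463-P464-A465-P466	SBD-beta	0.49	0.49	0.56	1	1	1
465	P464-A465-P466-R467	SBD-beta	0.65	0.50	0.63	1	1	1
519	D518-A519-E520-A521	SBD-alpha	0.22	0.65	0.05	1	1	1
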