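group	PAL	C4H	4CL	HCT	C3H	CSE	COMT	F5H	CCoAOMT	CCR	CAD
Zea mays	9	4	7	16	2	3	1	2	2	8	6
Oryza sativa	8	4	9	5	1	5	1	2	2	12	6
Arabidopsis thaliana	4	1	8	3	1	7	1	2	4	2	11
Solanum lycopersicum	10	3	9	23	5	5	5	1	13	2	9
Salix suchowensis	4	4	10	19	2	8	8	4	3	6	23
Salix purpurea	6	4	11	29	7	12	8	6	3	10	26
Populus euphratica	5	4	10	22	2	7	8	3	5	4	28
Populus trichocarpa	5	3	11	28	2	8	10	3	5	7	33
Salix matsudana	9	9	21	48	4	17	20	8	9	11	36
Salix matsudana At	2	3	8	22	2	6	6	2	2	3	20
Salix matsudana Bt	6	6	11	21	1	7	12	4	6	1	15
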