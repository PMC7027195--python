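EST Acc No.	Biosample	Cancer tissue	Length of EST	Swinger transformation	Acc No of aligned sequence	Chromosome	Gene	Aligned Seq. length	%ID	evalue	5'	3'
AI939983.1	SAMN00156802	Colon	379	A ↔ T	NC_000009.12	9	Non-coding region	360	97.778	4.32e−175	120,855,482	1,21E+08
AI939987.1	SAMN00156802	Colon	367	A ↔ T	NC_000009.12	9	Non-coding region	345	97.971	7.29e-168	120,855,464	1,21E+08
AW062766.1	SAMN00156993	Colon	457	A ↔ T	NC_000016.10	16	Non-coding region	313	99.681	9.49e−162	74,318,755	74319067
AW175734.1	SAMN00156993	Colon	328	A ↔ T	NC_000004.12	4	Non-coding region	136	90.441	1.12e−41	131,268,224	1,31E+08
AW175735.1	SAMN00156993	Colon	620	A ↔ T	NC_000004.12	4	Non-coding region	191	95.288	1.78e−79	131,268,167	1,31E+08
AW175739.1	SAMN00156993	Colon	222	A ↔ T	NC_000008.11	8	Non-coding region	139	97.122	1.83e−59	102,600,346	1,03E+08
AW175744.1	SAMN00156993	Colon	506	A ↔ T	NC_000008.11	8	Non-coding region	313	97.764	3.46e−151	88,009,959	88,009,648
AW903506.1	SAMN00159106	Nervous_normal	422	A → T → C → G → A	NC_000006.12	6	Non-coding region	350	97.143	8.28e−166	132,009,130	1,32E+08
AW903535.1	SAMN00159106	Nervous_normal	440	A → T → C → G → A	NC_000013.11	13	Non-coding region	442	99.321	0.0	95,650,104	95,650,545
AW903555.1	SAMN00159106	Nervous_normal	434	A → T → C → G → A	NC_000010.11	10	Non-coding region	436	99.312	0.0	20,554,187	20,553,752
AW903569.1	SAMN00159106	Nervous_normal	430	A → T → C → G → A	NC_000004.12	4	Non-coding region	357	98.599	1.36e−178	17,483,414	17,483,770
AW903572.1	SAMN00159106	Nervous_normal	248	A → T → C → G → A	NC_000013.11	13	Non-coding region	56	100.000	3.66e−20	95,650,461	95,650,406
BE085219.1	SAMN00159564	Breast	314	A → T → C → G → A	NC_000003.12	3	Non-coding region	311	97.749	3.94e−149	169,791,191	1,7E+08
BF332859.1	SAMN00160205	Breast	211	A → T → C → G → A	NC_000020.11	20	Non-coding region	143	90.210	2.12e−42	59,862,273	59,862,140
BF332861.1	SAMN00160205	Breast	364	A → T → C → G → A	NC_000010.11	10	Non-coding region	256	97.266	4.11e−119	8,810,014	8,810,267
BF354533.1	SAMN00160318	Head neck	388	A → T → C → G → A	NC_000005.10	5	Non-coding region	331	99.698	2.29e−171	69,932,968	69,933,298
BF370228.1	SAMN00160862	Prostate_normal	264	A → T → C → G → A	NC_000023.11	x	Non-coding region	195	95.897	2.01e−82	136,928,879	1,37E+08
AW062783.1	SAMN00156993	Colon	640	A ↔ T	NC_000009.12	9	Uncharacterized LOC101927086	557	75.404	5.09e−60	70,473,455	70,472,931
BF798648.1	SAMN00162090	Colon_ins	344	A ↔ T	NC_000003.12	3	Uncharacterized LOC102723512	148	96.622	2.87e−62	4,006,872	4,006,726
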