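#alleles POLRMT_1090 A T
#alleles POLRMT_1218 A G
#alleles ACO1_601 A G
#alleles NDUFA5_95 C T
#alleles LYRM4_51 A C
#alleles MARS2_298 C T
#alleles MARS2_345 G A
#alleles MARS2_498 G A
#alleles ACAD9_503 G A
sample_id	group	POLRMT_1090	POLRMT_1218	ACO1_601	NDUFA5_95	LYRM4_51	MARS2_298	MARS2_345	MARS2_498	ACAD9_503
CHN001	north	0	0	0	0	0	0	0	0	0
CHN002	north	0	0	0	0	0	0	0	0	0
CHN003	north	0	0	0	0	0	0	0	0	0
CHN004	north	0	0	0	0	0	0	0	0	0
CHN005	north	0	1	0	0	0	0	0	0	0
CHN006	north	0	1	0	0	0	0	0	0	0
CHN007	north	0	1	0	0	0	0	0	0	0
CHN008	north	0	1	1	0	0	0	0	0	0
CHN009	north	0	1	1	0	1	0	0	0	0
CHN010	north	0	1	1	0	1	0	0	0	0
CHN011	north	0	1	1	0	1	0	0	0	0
CHN012	north	0	1	1	0	1	0	0	0	0
CHN013	north	0	1	1	0	1	0	0	0	0
CHN014	north	0	1	1	0	1	0	0	0	0
CHN015	north	0	1	1	0	1	0	0	0	0
CHN016	north	0	1	1	0	1	0	0	0	0
CHN017	north	1	1	1	0	1	0	0	0	0
CHN018	north	1	1	1	0	1	0	0	0	0
CHN019	north	1	1	1	0	1	0	0	0	0
CHN020	north	1	1	1	0	1	0	0	0	0
CHN021	north	1	1	1	0	1	0	0	0	0
CHN022	north	1	1	1	0	1	0	0	0	0
CHN023	north	1	1	1	0	1	0	0	0	0
CHN024	north	1	1	2	0	1	0	0	0	0
CHN025	north	1	1	2	0	1	0	0	0	0
CHN026	north	1	2	2	0	1	0	0	0	0
CHN027	north	1	2	2	0	1	0	0	0	0
CHN028	north	1	2	2	0	1	0	0	0	0
CHN029	north	1	2	2	0	2	0	0	0	0
CHN030	north	1	2	2	0	2	0	0	0	1
CHN031	north	1	2	2	1	2	1	1	1	.
CHN032	north	1	2	2	1	2	1	1	1	.
CHN033	north	1	2	2	1	2	1	1	1	.
CHN034	north	2	2	2	1	2	1	1	1	.
CHN035	north	2	2	.	1	2	2	2	2	.
CHS001	south	0	1	1	0	0	0	0	0	0
CHS002	south	0	1	1	0	0	0	0	0	0
CHS003	south	1	1	1	0	0	0	0	0	0
CHS004	south	1	1	1	0	0	0	0	0	0
CHS005	south	1	1	1	0	0	0	0	0	0
CHS006	south	1	1	2	0	0	0	0	0	0
CHS007	south	1	1	2	0	0	0	0	0	0
CHS008	south	1	2	2	0	0	0	0	0	0
CHS009	south	1	2	2	0	0	0	0	0	0
CHS010	south	1	2	2	0	0	0	0	0	0
CHS011	south	1	2	2	0	0	0	0	0	0
CHS012	south	1	2	2	0	0	0	0	0	0
CHS013	south	1	2	2	1	0	0	0	0	0
CHS014	south	1	2	2	1	0	0	0	0	0
CHS015	south	1	2	2	1	0	1	0	0	0
CHS016	south	1	2	2	1	0	1	0	0	0
CHS017	south	1	2	2	1	0	1	0	0	0
CHS018	south	1	2	2	1	0	1	0	0	0
CHS019	south	1	2	2	1	0	1	0	0	0
CHS020	south	2	2	2	1	0	1	1	1	0
CHS021	south	2	2	2	1	0	1	1	1	0
CHS022	south	2	2	2	1	0	1	1	1	1
CHS023	south	2	2	2	1	0	1	1	1	1
CHS024	south	2	2	2	1	1	1	1	1	1
CHS025	south	2	2	2	1	1	1	1	1	1
CHS026	south	2	2	2	1	1	1	1	1	1
CHS027	south	2	2	2	1	1	1	1	1	1
CHS028	south	2	2	2	1	1	2	1	1	1
CHS029	south	2	2	2	1	1	2	1	1	1
CHS030	south	2	2	2	1	1	2	1	1	1
CHS031	south	2	2	2	2	1	2	1	1	1
CHS032	south	2	2	2	2	1	2	2	2	.
CHS033	south	2	2	2	2	2	.	2	2	.
CHS034	south	2	2	2	2	2	.	2	2	.
CHS035	south	2	2	2	2	2	.	2	2	.
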