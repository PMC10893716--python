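gene	probe_id	gene_section	status	logfc_m	ci_low	ci_high	abs_mean_diff	q_group	p_int_sex	p_int_age	p_gc
CRHR1	cg15607306	Body	Hypo	-0.066	-0.108	-0.023	0.004	0.049	0.87	0.91	0.77
POMC	cg09672383	5'UTR	Hypo	-0.082	-0.135	-0.03	0.018	0.049	0.70	0.62	0.11
MC2R	cg26344168	Body	Hypo	-0.07	-0.113	-0.027	0.011	0.049	0.44	0.52	0.83
NR3C1	cg26720913	5'UTR/1stExon	Hypo	-0.163	-0.265	-0.062	0.037	0.049	0.46	0.27	0.14
NR3C1	cg01967637	Promoter/5'UTR/1stExon	Hyper	0.1	0.037	0.163	0.02	0.049	0.33	0.84	0.080
NR3C1	cg15910486	Promoter/5'UTR	Hyper	0.09	0.039	0.141	0.02	0.033	0.64	0.87	0.62
FKBP5	cg23416081	5'UTR	Hypo	-0.292	-0.432	-0.152	0.055	0.0052	0.54	0.48	0.017
FKBP5	cg15929276	5'UTR	Hypo	-0.252	-0.397	-0.107	0.051	0.037	0.36	0.83	0.0045
FKBP5	cg03591753	5'UTR	Hypo	-0.132	-0.176	-0.088	0.031	0.00001	0.58	0.0060	0.26
FKBP5	cg20813374	Promoter/5'UTR	Hypo	-0.126	-0.183	-0.07	0.02	0.0019	0.91	0.055	0.60
FKBP5	cg03546163	5'UTR	Hypo	-0.178	-0.248	-0.108	0.029	0.00012	0.97	0.00063	0.92
FKBP5	cg01839003	5'UTR	Hypo	-0.077	-0.125	-0.029	0.007	0.049	0.37	0.11	0.036
FKBP5	cg22363520	Body	Hypo	-0.253	-0.338	-0.167	0.017	0.00001	0.83	0.10	0.068
HSD11B1	cg06571187	Promoter/5'UTR	Hypo	-0.108	-0.177	-0.039	0.017	0.049	0.94	0.027	0.18
HSD11B1	cg14139038	Promoter/5'UTR	Hypo	-0.078	-0.118	-0.039	0.01	0.0098	0.42	0.0020	0.49
SRD5A1	cg22911074	Promoter	Hyper	0.081	0.031	0.13	0.01	0.049	0.72	0.90	0.018
AKR1D1	cg02118020	Body	Hyper	0.188	0.067	0.31	0.047	0.049	0.25	0.25	0.017
AKR1D1	cg05082563	Body	Hypo	-0.127	-0.208	-0.046	0.024	0.049	0.81	0.67	0.11
AKR1D1	cg27250318	Body	Hypo	-0.181	-0.29	-0.071	0.033	0.049	0.70	0.42	0.16
AKR1D1	cg09373725	Body	Hypo	-0.098	-0.159	-0.038	0.015	0.049	0.82	0.22	0.45
DUSP1	cg00593243	Body	Hyper	0.184	0.071	0.297	0.042	0.049	0.28	0.34	0.11
TSC22D3	cg26954928	Body	Hypo	-0.099	-0.161	-0.037	0.002	0.049	0.38	0.061	0.41
TSC22D3	cg11907074	Promoter/Body	Hyper	0.114	0.052	0.176	0.008	0.020	0.86	0.56	0.69
TNF	cg10650821	1stExon	Hypo	-0.059	-0.09	-0.029	0.014	0.012	0.82	0.45	0.17
TNF	cg26729380	1stExon	Hypo	-0.052	-0.085	-0.019	0.01	0.049	0.75	0.80	0.66
TNF	cg08553327	1stExon	Hypo	-0.062	-0.099	-0.025	0.01	0.049	0.89	0.49	0.28
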