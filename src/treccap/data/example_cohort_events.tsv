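sample_id	partner_gene	event_class
P0001	KDM5A	translocation_type2
P0001	TLX1	translocation_type2
P0002	AKT2	translocation_type2
P0002	TLX1	translocation_type2
P0003	LYL1	translocation_type2
P0003	TLX1	translocation_type2
P0004	OLIG2	translocation_type2
P0004	TLX1	translocation_type2
P0005	MYB	translocation_type2
P0005	TLX1	translocation_type2
P0006	CCND2	translocation_type2
P0006	TLX1	translocation_type2
P0007	PTCRA	translocation_type2
P0007	TLX1	translocation_type2
P0008	TLX1	translocation_type2
P0009	TLX1	translocation_type2
P0010	TLX1	translocation_type2
P0011	TLX1	translocation_type2
P0012	TLX1	translocation_type2
P0013	TLX1	translocation_type2
P0014	TLX1	translocation_type2
P0015	TLX1	translocation_type2
P0016	TLX1	translocation_type2
P0017	TLX1	translocation_type2
P0018	TLX1	translocation_type2
P0019	TLX1	translocation_type2
P0020	TLX1	translocation_type2
P0021	TLX1	translocation_type2
P0022	TLX1	translocation_type2
P0023	TLX1	translocation_type2
P0024	TLX1	translocation_type2
P0025	TLX1	translocation_type2
P0026	TLX1	translocation_type2
P0027	TLX1	translocation_type2
P0028	TLX1	translocation_type2
P0029	TLX1	translocation_type2
P0030	TLX1	translocation_type2
P0031	TLX1	translocation_type2
P0032	TLX1	translocation_type2
P0033	TLX1	translocation_type2
P0034	TLX1	translocation_type2
P0035	TLX1	translocation_type2
P0036	TLX1	translocation_type2
P0037	TLX1	translocation_type2
P0038	TLX1	translocation_type2
P0039	TLX1	translocation_type2
P0040	TLX1	translocation_type2
P0041	TLX1	translocation_type2
P0042	TLX1	translocation_type2
P0043	TLX1	translocation_type2
P0044	TLX1	translocation_type2
P0045	TLX1	translocation_type2
P0046	TLX1	translocation_type2
P0047	TLX1	translocation_type2
P0048	TLX1	translocation_type2
P0049	TLX1	translocation_type2
P0050	TLX1	translocation_type2
P0051	TLX1	translocation_type2
P0052	TLX1	translocation_type2
P0053	TLX1	translocation_type2
P0054	TLX1	translocation_type2
P0055	TLX1	translocation_type2
P0056	TLX1	translocation_type2
P0057	TLX1	translocation_type2
P0058	TLX1	translocation_type2
P0059	TLX1	translocation_type2
P0060	TLX1	translocation_type2
P0061	TLX1	translocation_type2
P0062	TLX1	translocation_type2
P0063	TLX1	translocation_type2
P0064	TLX1	translocation_type2
P0065	TLX1	translocation_type2
P0066	TLX1	translocation_type2
P0067	TLX1	translocation_type2
P0068	TLX1	translocation_type2
P0069	TLX1	translocation_type2
P0070	TLX1	translocation_type2
P0071	TLX1	translocation_type2
P0072	TLX1	translocation_type2
P0073	TLX1	translocation_type2
P0074	TLX1	translocation_type2
P0075	TLX1	translocation_type2
P0076	TLX1	translocation_type2
P0077	TLX1	translocation_type2
P0078	TLX1	translocation_type2
P0079	TLX1	translocation_type2
P0080	TLX1	translocation_type2
P0081	TLX1	translocation_type2
P0082	TLX1	translocation_type2
P0083	TLX1	translocation_type2
P0084	TLX1	translocation_type2
P0085	TLX1	translocation_type2
P0086	TLX1	translocation_type2
P0087	TLX1	translocation_type2
P0088	TLX1	translocation_type2
P0089	TLX1	translocation_type2
P0090	TLX1	translocation_type2
P0091	TLX1	translocation_type2
P0092	TLX1	translocation_type2
P0093	TLX1	translocation_type2
P0094	TLX1	translocation_type2
P0095	TLX1	translocation_type2
P0096	LMO2	translocation_type2
P0097	LMO2	translocation_type2
P0098	LMO2	translocation_type2
P0099	LMO2	translocation_type2
P0100	LMO2	translocation_type2
P0101	LMO2	translocation_type2
P0102	LMO2	translocation_type2
P0103	LMO2	translocation_type2
P0104	LMO2	translocation_type2
P0105	LMO2	translocation_type2
P0106	LMO2	translocation_type2
P0107	LMO2	translocation_type2
P0108	LMO2	translocation_type2
P0109	LMO2	translocation_type2
P0110	LMO2	translocation_type2
P0111	LMO2	translocation_type2
P0112	LMO2	translocation_type2
P0113	LMO2	translocation_type2
P0114	LMO2	translocation_type2
P0115	LMO2	translocation_type2
P0116	LMO2	translocation_type2
P0117	LMO2	translocation_type2
P0118	LMO2	translocation_type2
P0119	LMO2	translocation_type2
P0120	LMO2	translocation_type2
P0121	LMO2	translocation_type2
P0122	LMO2	translocation_type2
P0123	LMO2	translocation_type2
P0124	LMO2	translocation_type2
P0125	LMO2	translocation_type2
P0126	LMO2	translocation_type2
P0127	LMO2	translocation_type2
P0128	LMO2	translocation_type2
P0129	LMO2	translocation_type2
P0130	LMO2	translocation_type2
P0131	LMO2	translocation_type2
P0132	LMO2	translocation_type2
P0133	LMO2	translocation_type2
P0134	LMO2	translocation_type2
P0135	LMO2	translocation_type2
P0136	LMO2	translocation_type2
P0137	LMO2	translocation_type2
P0138	LMO2	translocation_type2
P0139	LMO2	translocation_type2
P0140	LMO2	translocation_type2
P0141	LMO2	translocation_type2
P0142	LMO2	translocation_type2
P0143	LMO2	translocation_type2
P0144	LMO2	translocation_type2
P0145	LMO2	translocation_type2
P0146	LMO2	translocation_type2
P0147	LMO2	translocation_type2
P0148	TAL1	translocation_type2
P0149	TAL1	translocation_type2
P0150	TAL1	translocation_type2
P0151	TAL1	translocation_type2
P0152	TAL1	translocation_type2
P0153	TAL1	translocation_type2
P0154	TAL1	translocation_type2
P0155	TAL1	translocation_type2
P0156	TAL1	translocation_type2
P0157	TAL1	translocation_type2
P0158	TAL1	translocation_type2
P0159	TAL1	translocation_type2
P0160	TAL1	translocation_type2
P0161	TAL1	translocation_type2
P0162	TAL1	translocation_type2
P0163	TAL1	translocation_type2
P0164	TAL1	translocation_type2
P0165	TAL1	translocation_type2
P0166	TAL1	translocation_type2
P0167	TAL1	translocation_type2
P0168	TAL1	translocation_type2
P0169	TAL1	translocation_type2
P0170	TAL1	translocation_type2
P0171	ZFP36L2	TREC_insertion
P0172	ZFP36L2	TREC_insertion
P0173	ZFP36L2	TREC_insertion
P0174	ZFP36L2	TREC_insertion
P0175	ZFP36L2	TREC_insertion
P0176	ZFP36L2	TREC_insertion
P0177	ZFP36L2	TREC_insertion
P0178	ZFP36L2	TREC_insertion
P0179	ZFP36L2	TREC_insertion
P0180	ZFP36L2	TREC_insertion
P0181	ZFP36L2	TREC_insertion
P0182	LMO1	translocation_type2
P0183	LMO1	translocation_type2
P0184	LMO1	translocation_type2
P0185	LMO1	translocation_type2
P0186	TLX3	translocation_type2
P0187	TLX3	translocation_type2
P0188	TLX3	translocation_type2
P0189	TLX3	translocation_type2
P0190	mtDNA	translocation_type2
P0191	mtDNA	translocation_type2
P0192	mtDNA	translocation_type2
P0193	NOTCH1	translocation_type2
P0194	NOTCH1	translocation_type2
P0195	NOTCH1	translocation_type2
P0196	NKX2-4	translocation_type2
P0197	NKX2-4	translocation_type2
P0198	RPP30	translocation_type2
P0199	ROCK1	translocation_type2
P0200	SNAI2	translocation_type2
P0201	SORCS1	translocation_type2
P0202	HOTAIR	translocation_type2
P0203	MORN3	translocation_type2
P0204	LAMA4	translocation_type2
P0205	FHIT	translocation_type2
P0206	CTNNA2	translocation_type2
P0207	DDIT3	translocation_type2
P0208	WIF1	translocation_type2
P0209	BCL11B	translocation_type2
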