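Accession	Gene	Pep_bait	TSC_bait	Pep_ctrl	TSC_ctrl
P001	ETAA1	5	30	2	5
P002	ATRIP	3	9	1	3
P003	SMARCAL1	4	20	0	0
P004	SMARCAL1	2	5	2	4
P005	MCM8IP	2	12	1	2
P006	RPA2	6	40	3	10
P007	TOPBP1	3	15	2	5
P008	TOPBP1	3	6	2	5
P009	RFWD3	2	8	0	0
P010	PC	10	100	1	2
P011	MCCC1	4	30	1	1
P012	KRT1	1	50	1	1
P013	ACTB	8	30	6	15
P014	TUBB	5	8	2	3
P015	GAPDH	4	11	2	4
P016	HSPA8	3	9	2	4
P017	EEF1A1	2	5	1	2
P018	VIM	0	0	0	0
P019	HIST1H1C	1	2	0	0
P020	LMNA	2	8	2	3
P021	PRDX1	0	0	1	2
P022	ANXA2	2	6	2	6
P023	RPL10	4	12	3	10
P024	RPS3	2	4	1	3
P025	MYH9	6	20	3	8
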