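genome	LacI	ROK	RpiR	DeoR/SorC	BglG	TetR	TetR_all	AraC	AraC_all	GntR	GntR_all	Total	CUG_pct
B. adolescentis	18	4	0	1	1	6	10	2	4	1	10	33	11.6
B. angulatum	19	4	0	1	1	2	9	1	2	0	8	28	11.2
B. animalis	11	4	0	1	0	2	15	0	1	0	18	18	10
B. bifidum	11	4	1	2	1	0	6	0	2	2	11	21	9.3
B. breve DSM 20213	23	7	1	1	1	2	9	2	3	1	12	38	13
B. breve UCC2003	30	6	1	1	1	2	7	0	1	1	12	42	14.1
B. dentium	34	6	0	1	1	7	16	2	6	3	13	54	15.5
B. gallicum	7	3	0	1	0	0	3	0	0	1	9	12	9.2
B. longum NCC2705	21	6	1	1	1	1	6	0	0	0	9	31	11.6
B. longum ATCC 15697	20	5	1	1	1	1	8	1	2	1	12	31	11.8
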