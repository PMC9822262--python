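kinase	class	hit_rate	potts_penalty	dg_reorg	dg_reorg_err
MELK	STK	3	5.9	5.6	0.2
MAPK9	STK	5	4.7	6.9	0.3
CDK2	STK	2	5.3	7.7	0.2
IRAK4	STK	0	2.5	5.4	0.2
BRAF	STK	7	4.0	6.5	0.1
ABL1	TK	10	-1.0	1.3	0.3
LCK	TK	11	0.5	1.0	0.3
TIE2	TK	6	1.1	-0.3	0.2
NTRK2	TK	6	-1.0	1.7	0.1
DDR1	TK	11	0.4	0.3	0.3
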